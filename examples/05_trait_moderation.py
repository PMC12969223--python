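"""Robust moderation analysis: does neuroticism moderate the association
between trait RNT and CAP occupancy?

Runs the full pipeline on a synthetic study with a planted negative
rnt x neuroticism interaction on the default-mode-like state, then fits
occupancy ~ rnt * neu + age + sex with a Tukey-bisquare MM-estimator and
bootstrap CIs, and probes the interaction with simple slopes at +/-1 SD of
neuroticism.
"""

import numpy as np

import capdyn as cd
from capdyn.calibration import run_pipeline_moderation

report = run_pipeline_moderation(seed=7, n_subjects=48, n_boot=2000)
print(f"outcome: RNT-condition occupancy of the DMN-like CAP (n = {report.n})")
print("\nB (unstandardized), beta, 95% bootstrap CI, bootstrap p:")
print(report.terms.round(4).to_string())

slopes = cd.simple_slopes(report)
print("\nsimple slopes of rnt at neuroticism = mean -/+ 1 SD:")
print(slopes.round(4).to_string(index=False))
print("\nA negative interaction means the rnt-occupancy association is more "
      "negative (here: weaker/reversed) for subjects high in neuroticism, "
      "matching the planted coefficient (-0.45 on the occupancy logit).")

q = cd.fdr_adjust(report.terms["p"].to_numpy())
print("\nBH-FDR q-values over this model's terms:", np.round(q, 4))
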