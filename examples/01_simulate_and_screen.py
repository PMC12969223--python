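"""Generate a synthetic study and apply participant-level QC screening.

Builds a small blocked RUM/WOR/DIS task-fMRI study with five planted brain
states, then screens a 122-subject QC roster with the standard exclusion
rules (>4 mm mean absolute motion, visual artifacts, <2 of 3 attention
items correct).
"""

import capdyn as cd

config = cd.StudyConfig(n_subjects=8, frames_per_block=40, grid=(11, 11, 9), seed=7)
study = cd.simulate_study(config)
print(f"subjects: {config.n_subjects}, frames/block: {config.frames_per_block}, "
      f"in-mask voxels: {study.truth.mask_voxel_ids.size}")
print(f"planted states: {config.k_true} "
      f"(networks: {[n or 'edge artifact' for n in study.truth.state_networks]})")
print("\ntiming table (first subject):")
print(study.timing.head(3).to_string(index=False))

roster = cd.make_qc_roster(122, n_motion_fail=10, n_attention_fail=2, seed=7)
included, log = cd.screen(roster, motion_limit_mm=4.0)
print(f"\nQC: {len(roster)} scanned, {len(log)} excluded "
      f"({log['reason'].value_counts().to_dict()}), {len(included)} analyzable")
# A subject passes iff motion <= 4 mm, no artifact, and >= 2 attention items.
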