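"""Seeded recovery and calibration experiments on synthetic studies.

These experiments quantify, on generated data with known truth, the
behavior the pipeline promises: recovery of the planted number of states by
PAC model selection, recovery of the planted maps by the final clustering,
frequentist calibration of the bootstrap and permutation machinery, the
robustness advantage of the MM-estimator under contamination, and
end-to-end recovery of a planted trait-interaction sign.

Problem sizes are deliberately modest (hundreds of frames, a few hundred
voxels, tens of subjects) so the full battery runs in minutes on one core;
each experiment is deterministic given its base seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import consensus, evaluation, extraction, metrics, stats, synthetic

#: fast-S settings used inside heavy replication loops
FAST_FIT = dict(n_subsets=10, s_refine=1)


def recovery_config(seed: int, n_subjects: int = 8, noise_sd: float = 0.5) -> synthetic.StudyConfig:
    """Reduced study used by recovery experiments: three 40-frame blocks per
    subject on an ~320-voxel grid, five latent states (one edge artifact)."""
    return synthetic.StudyConfig(n_subjects=n_subjects, frames_per_block=40,
                                 grid=(11, 11, 9), noise_sd=noise_sd, seed=seed)


def _frames(study):
    return extraction.extract_blocks(study.images, study.timing, study.mask_img)


def k_recovery_rate(n_seeds: int = 20, base_seed: int = 0) -> float:
    """Share of seeded studies for which PAC consensus selects k_true."""
    hits = 0
    for i in range(n_seeds):
        cfg = recovery_config(seed=base_seed + i)
        study = synthetic.simulate_study(cfg)
        results = consensus.consensus_cluster(_frames(study), seed=base_seed + i)
        hits += consensus.select_k(results) == cfg.k_true
    return hits / n_seeds


def centroid_recovery(seed: int = 0, n_folds: int = 10) -> np.ndarray:
    """Hungarian-matched correlations between final centroids and the
    planted maps (their image under the pipeline's block normalization)."""
    cfg = recovery_config(seed=seed)
    study = synthetic.simulate_study(cfg)
    fm = _frames(study)
    caps = consensus.finalize_caps(fm, cfg.k_true, n_folds=n_folds, seed=seed + 1)
    reference = evaluation.planted_signatures(fm, study.truth)
    _, corr = evaluation.match_states(caps.centroids, reference)
    return corr


def bootstrap_coverage(n_reps: int = 200, n: int = 110, n_boot: int = 400,
                       base_seed: int = 0) -> float:
    """Coverage of the 95% percentile bootstrap CI for a null slope."""
    covered = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + rep)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = rng.normal(size=n)
        draws = stats.bootstrap_coefs(y, X, n_boot=n_boot, seed=base_seed + rep,
                                      **FAST_FIT)
        lo, hi = stats.percentile_ci(draws)[1]
        covered += lo <= 0.0 <= hi
    return covered / n_reps


def permutation_type1(n_reps: int = 100, n: int = 110, n_perm: int = 199,
                      base_seed: int = 0) -> float:
    """Rejection rate of the Freedman–Lane quadratic-term test at alpha=.05
    when the true model is purely linear."""
    rejected = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(10_000 + base_seed + rep)
        df = pd.DataFrame({
            "rnt": rng.normal(size=n), "neu": rng.normal(size=n),
            "age": rng.normal(23, 4, n), "sex": rng.integers(0, 2, n),
        })
        df["y"] = 0.4 * df["rnt"] + 0.2 * df["neu"] + rng.normal(size=n)
        mc = stats.compare_polynomial(df, "y", n_boot=20, n_perm=n_perm,
                                      seed=base_seed + rep, **FAST_FIT)
        rejected += mc.p_perm < 0.05
    return rejected / n_reps


def contamination_advantage(n_reps: int = 100, n: int = 150,
                            outlier_fraction: float = 0.1,
                            base_seed: int = 0) -> float:
    """Share of replications where the MM slope beats OLS under gross
    high-leverage outliers on 10% of the observations."""
    wins = 0
    n_bad = int(round(outlier_fraction * n))
    for rep in range(n_reps):
        rng = np.random.default_rng(20_000 + base_seed + rep)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 * x + rng.normal(size=n)
        y[np.argsort(x)[-n_bad:]] += 20.0
        mm = stats.mm_fit(y, X, **FAST_FIT).coef[1]
        ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        wins += abs(mm - 2.0) < abs(ols - 2.0)
    return wins / n_reps


def run_pipeline_moderation(seed: int, n_subjects: int = 48,
                            n_boot: int = 0) -> stats.FitReport:
    """Full pipeline on one synthetic study, ending in the moderation fit
    for the trait-carrying state's RNT occupancy.

    Clustering runs at the planted k (model-order selection is exercised by
    :func:`k_recovery_rate`); the recovered CAP is matched to the planted
    state by centroid correlation before its occupancy enters the model.
    """
    cfg = recovery_config(seed=seed, n_subjects=n_subjects)
    study = synthetic.simulate_study(cfg)
    fm = _frames(study)
    caps = consensus.finalize_caps(fm, cfg.k_true, n_folds=2, seed=seed + 1)
    reference = evaluation.planted_signatures(fm, study.truth)
    assignment, _ = evaluation.match_states(caps.centroids, reference)
    target_state = cfg.trait_effects[0].state
    cap_id = int(np.flatnonzero(assignment == target_state)[0]) + 1
    table = metrics.rnt_contrast(
        metrics.temporal_metrics(caps.assignments, fm.frame_index, cfg.k_true))
    occ = table[(table["condition"] == "RNT") & (table["cap"] == cap_id)]
    df = study.phenotypes.merge(occ[["subject", "occupancy"]], on="subject")
    return stats.moderation(df, "occupancy", n_boot=n_boot, seed=seed, **FAST_FIT)


def interaction_sign_recovery(n_runs: int = 20, base_seed: int = 0) -> float:
    """Share of end-to-end runs recovering the planted negative interaction."""
    negative = 0
    for i in range(n_runs):
        report = run_pipeline_moderation(seed=base_seed + 31 * i)
        negative += report.terms.loc["rnt_x_neu", "B"] < 0
    return negative / n_runs
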