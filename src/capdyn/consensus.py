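"""Consensus k-means clustering of fMRI frames with PAC model selection.

The number of coactivation patterns is chosen by consensus clustering:
for each candidate k, many k-means runs on random 80% subsamples (drawn
without replacement) are accumulated into a consensus matrix of pairwise
co-assignment frequencies among co-sampled frames.  The proportion of
ambiguously clustered pairs (PAC) — pairs whose consensus falls strictly
between the lower and upper thresholds — is the cost; the k minimizing PAC
wins, with ties broken toward the smaller k.  The final solution re-runs
k-means on all frames over many restarts and keeps the minimum-inertia fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, InputError
from .extraction import FrameMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = range(4, 12)
PAC_THRESHOLDS = (0.1, 0.9)


@dataclass
class CAPSet:
    """A fitted set of coactivation patterns.

    ``assignments`` are 0-based labels (CAP ``c`` corresponds to label
    ``c - 1``); each centroid is exactly the mean of its member frames.
    """

    k: int
    centroids: np.ndarray          # (k, n_voxels) z-units
    assignments: np.ndarray        # (n_frames,) int
    inertia: float

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


@dataclass
class ConsensusResult:
    """Consensus matrix and PAC value for one candidate k."""

    k: int
    consensus: np.ndarray          # (n, n) float32; NaN where never co-sampled
    pac: float
    n_runs: int
    subsample_fraction: float
    n_undefined_pairs: int = 0
    runs: list | None = field(default=None, repr=False)   # optional (indices, labels) log


def _as_array(frames) -> np.ndarray:
    if isinstance(frames, FrameMatrix):
        return frames.data
    return np.asarray(frames, dtype=np.float64)


def kmeans_frames(frames, k: int, n_restarts: int = 1, seed: int = 0,
                  max_iter: int = 300) -> CAPSet:
    """Minimum-inertia Lloyd k-means over ``n_restarts`` k-means++ starts."""
    X = _as_array(frames)
    if k < 2:
        raise InputError("k must be at least 2")
    if X.shape[0] < k:
        raise DegenerateInputError(f"{X.shape[0]} frames cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, algorithm="lloyd",
                max_iter=max_iter, random_state=np.random.default_rng(seed).integers(2**31))
    labels = km.fit_predict(X)
    if np.unique(labels).size < k:
        raise DegenerateInputError(
            f"only {np.unique(labels).size} distinct clusters found for k={k}; "
            "data has too few distinct frames")
    # enforce the centroid-equals-member-mean invariant exactly
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    inertia = float(((X - centroids[labels]) ** 2).sum())
    return CAPSet(k=k, centroids=centroids, assignments=labels, inertia=inertia)


def pac_from_consensus(consensus: np.ndarray, thresholds=PAC_THRESHOLDS) -> float:
    """PAC = share of defined (co-sampled) pairs with consensus strictly
    inside the ambiguity band."""
    lo, hi = thresholds
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    defined = ~np.isnan(vals)
    if defined.sum() == 0:
        raise InputError("no frame pair was ever co-sampled")
    vals = vals[defined]
    return float(np.mean((vals > lo) & (vals < hi)))


def consensus_cluster(frames, k_range=DEFAULT_K_RANGE, n_runs: int = 50,
                      subsample_fraction: float = 0.8, seed: int = 0,
                      thresholds=PAC_THRESHOLDS,
                      keep_runs: bool = False) -> list[ConsensusResult]:
    """Consensus clustering over a range of k.

    Each run draws ``subsample_fraction`` of the frames without replacement,
    clusters them with a single k-means++ start, and accumulates co-sampling
    and co-assignment counts.  Child seeds are derived per (k, run) from the
    master seed, so results do not depend on execution order.  Pairs never
    co-sampled are excluded from the PAC denominator (and counted).
    """
    X = _as_array(frames)
    n = X.shape[0]
    if not 0 < subsample_fraction < 1:
        raise InputError("subsample_fraction must lie in (0, 1)")
    m = int(round(subsample_fraction * n))
    k_range = list(k_range)
    if not k_range:
        raise InputError("empty k range")
    if max(k_range) > m:
        raise InputError(f"largest k={max(k_range)} exceeds subsample size {m}")

    results = []
    for k in k_range:
        co_sampled = np.zeros((n, n), dtype=np.float32)
        co_assigned = np.zeros((n, n), dtype=np.float32)
        run_log = [] if keep_runs else None
        for run in range(n_runs):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(k, run))
            rng = np.random.default_rng(child)
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init=1, algorithm="lloyd",
                        random_state=int(rng.integers(2**31)))
            labels = km.fit_predict(X[idx])
            co_sampled[np.ix_(idx, idx)] += 1
            for c in range(k):
                members = idx[labels == c]
                co_assigned[np.ix_(members, members)] += 1
            if keep_runs:
                run_log.append((idx, labels))
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = co_assigned / co_sampled
        consensus[co_sampled == 0] = np.nan
        iu = np.triu_indices(n, k=1)
        n_undefined = int(np.isnan(consensus[iu]).sum())
        if n_undefined:
            logger.info("k=%d: %d frame pairs never co-sampled; excluded from PAC",
                        k, n_undefined)
        results.append(ConsensusResult(
            k=k, consensus=consensus, pac=pac_from_consensus(consensus, thresholds),
            n_runs=n_runs, subsample_fraction=subsample_fraction,
            n_undefined_pairs=n_undefined, runs=run_log))
    return results


def select_k(results: list[ConsensusResult]) -> int:
    """k with minimal PAC; ties go to the smaller k."""
    if not results:
        raise InputError("no consensus results to select from")
    best = min(results, key=lambda r: (r.pac, r.k))
    ties = [r.k for r in results if r.pac == best.pac]
    if len(ties) > 1:
        logger.info("PAC tie among k=%s; selecting smallest k=%d", ties, best.k)
    return best.k


def finalize_caps(frames, k: int, n_folds: int = 100, seed: int = 0) -> CAPSet:
    """Final CAP solution: all frames, ``n_folds`` restarts, minimum inertia."""
    return kmeans_frames(frames, k, n_restarts=n_folds, seed=seed)
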