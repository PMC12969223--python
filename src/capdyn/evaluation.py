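"""Recovery evaluation against synthetic ground truth.

Cluster labels are arbitrary, so estimated CAPs are matched to planted
states by maximizing total spatial correlation (Hungarian assignment).
Because clustering operates on per-block z-normalized frames, the planted
map's image in that space is the state-conditional mean of the normalized
frames — computed here from the generator's true state sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .consensus import CAPSet
from .extraction import FrameMatrix
from .synthetic import GroundTruth


def true_state_labels(fm: FrameMatrix, truth: GroundTruth) -> np.ndarray:
    """Planted state label for every frame of a FrameMatrix."""
    labels = np.empty(fm.n_frames, dtype=np.int64)
    for subject, condition, idx in fm.blocks():
        seq = truth.state_sequences[(subject, condition)]
        pos = fm.frame_index.loc[idx, "position"].to_numpy()
        labels[idx] = seq[pos]
    return labels


def planted_signatures(fm: FrameMatrix, truth: GroundTruth) -> np.ndarray:
    """State-conditional mean of the normalized frames (k_true x voxels)."""
    labels = true_state_labels(fm, truth)
    return np.stack([fm.data[labels == s].mean(axis=0) for s in range(truth.k_true)])


def match_states(centroids: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of centroids to reference maps by correlation.

    Returns (reference index per centroid, matched correlations).  Handles
    unequal counts by matching min(k, k_ref) pairs; unmatched centroids get
    reference -1 and correlation NaN.
    """
    k, k_ref = centroids.shape[0], reference.shape[0]
    corr = np.empty((k, k_ref))
    for i in range(k):
        for j in range(k_ref):
            corr[i, j] = np.corrcoef(centroids[i], reference[j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    assignment = np.full(k, -1, dtype=int)
    matched_corr = np.full(k, np.nan)
    assignment[rows] = cols
    matched_corr[rows] = corr[rows, cols]
    return assignment, matched_corr


def assignment_accuracy(caps: CAPSet, fm: FrameMatrix, truth: GroundTruth) -> float:
    """Share of frames whose CAP label matches the planted state after
    Hungarian matching of centroids to planted signatures."""
    reference = planted_signatures(fm, truth)
    assignment, _ = match_states(caps.centroids, reference)
    mapped = assignment[caps.assignments]
    return float(np.mean(mapped == true_state_labels(fm, truth)))
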