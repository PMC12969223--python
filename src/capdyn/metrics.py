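"""Temporal CAP metrics: counts, persistence, occupancy, and the RNT
average / RNT > DIS contrast.

Counts are the number of volumes a subject-condition block spends in each
CAP; a visit is a maximal run of identical labels, and persistence is the
mean visit duration in volumes (so counts = persistence x n_visits).  A CAP
never entered in a block has counts 0 and *missing* persistence — zero
would conflate "never entered" with "entered for an instant".  Metrics from
the rumination and worry blocks are averaged into an RNT condition
(averaging rather than summing keeps the original scale), and the
RNT > DIS contrast subtracts the distraction block.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

RAW_CONDITIONS = ("RUM", "WOR", "DIS")
METRIC_COLUMNS = ("counts", "n_visits", "persistence", "occupancy")


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(label, length) of each maximal run in a label sequence."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InputError("empty label sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def temporal_metrics(assignments: np.ndarray, frame_index: pd.DataFrame,
                     k: int, tr_seconds: float | None = None) -> pd.DataFrame:
    """Per (subject, condition, cap) counts, visits, persistence, occupancy.

    ``assignments`` are 0-based frame labels aligned with ``frame_index``
    (as produced by clustering); the output ``cap`` column is 1-based.
    An optional TR multiplier converts persistence to seconds.
    """
    assignments = np.asarray(assignments)
    if len(frame_index) == 0:
        raise InputError("empty block")
    if len(assignments) != len(frame_index):
        raise InputError("assignments and frame_index disagree in length")
    rows = []
    for (subject, condition), idx in frame_index.groupby(
            ["subject", "condition"], sort=False).groups.items():
        idx = np.asarray(idx)
        labels = assignments[idx]
        length = labels.size
        if length == 0:
            raise InputError(f"empty block for {subject}/{condition}")
        visit_labels, visit_lengths = run_lengths(labels)
        for cap in range(k):
            counts = int((labels == cap).sum())
            mine = visit_lengths[visit_labels == cap]
            n_visits = int(mine.size)
            persistence = float(mine.mean()) if n_visits else np.nan
            if tr_seconds is not None and n_visits:
                persistence *= tr_seconds
            rows.append((subject, condition, cap + 1, counts, n_visits,
                         persistence, counts / length))
    return pd.DataFrame(rows, columns=["subject", "condition", "cap", *METRIC_COLUMNS])


def rnt_contrast(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append RNT = (RUM + WOR)/2 and RNT_gt_DIS = RNT - DIS rows.

    Missing persistence propagates as missing.  Subject-cap pairs lacking a
    raw condition are skipped with a log entry.
    """
    wide = metrics.pivot_table(index=["subject", "cap"], columns="condition",
                               values=list(METRIC_COLUMNS), dropna=False)
    new_rows = []
    for (subject, cap), row in wide.iterrows():
        missing_conditions = [c for c in RAW_CONDITIONS
                              if ("counts", c) not in row.index or pd.isna(row[("counts", c)])]
        if missing_conditions:
            logger.info("skipping %s/cap %s: missing conditions %s",
                        subject, cap, missing_conditions)
            continue
        rnt = {m: (row[(m, "RUM")] + row[(m, "WOR")]) / 2 for m in METRIC_COLUMNS}
        diff = {m: rnt[m] - row[(m, "DIS")] for m in METRIC_COLUMNS}
        new_rows.append((subject, "RNT", cap, *[rnt[m] for m in METRIC_COLUMNS]))
        new_rows.append((subject, "RNT_gt_DIS", cap, *[diff[m] for m in METRIC_COLUMNS]))
    if not new_rows:
        return metrics.copy()
    derived = pd.DataFrame(new_rows, columns=["subject", "condition", "cap", *METRIC_COLUMNS])
    return pd.concat([metrics, derived], ignore_index=True)


def metrics_for_stats(metrics: pd.DataFrame, condition: str, metric: str,
                      cap: int) -> pd.DataFrame:
    """One row per subject with the chosen metric as column ``value``."""
    sub = metrics[(metrics["condition"] == condition) & (metrics["cap"] == cap)]
    return sub[["subject", metric]].rename(columns={metric: "value"}).reset_index(drop=True)
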