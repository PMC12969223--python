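"""Participant-level quality-control screening.

A subject enters the analysis sample iff mean absolute head motion does not
exceed the limit (strict ``> limit`` excludes), no visual-inspection artifact
was flagged, and at least two of three embedded attention-check items were
answered correctly.  Imaging failures take precedence over attention failures
in the exclusion log, matching the sequential bookkeeping of imaging QC
before the self-report check.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

REASON_MOTION = "MOTION"
REASON_ARTIFACT = "ARTIFACT"
REASON_ATTENTION = "ATTENTION"

_COLUMNS = ("subject", "mean_abs_motion", "artifact_flag", "attention_correct")


def _validate(roster: pd.DataFrame) -> pd.DataFrame:
    if len(roster) == 0:
        raise InputError("QC roster is empty")
    missing = [c for c in _COLUMNS if c not in roster.columns]
    if missing:
        raise InputError(f"QC roster lacks columns: {missing}")
    if roster["subject"].duplicated().any():
        dupes = roster.loc[roster["subject"].duplicated(), "subject"].tolist()
        raise InputError(f"duplicate subject identifiers: {dupes}")
    if (roster["mean_abs_motion"] < 0).any():
        raise InputError("mean_abs_motion must be non-negative")
    att = roster["attention_correct"]
    if ((att < 0) | (att > 3)).any():
        raise InputError("attention_correct must lie in 0..3")
    return roster


def screen(roster: pd.DataFrame, motion_limit_mm: float = 4.0,
           min_attention_correct: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules; return (included roster, exclusion log).

    The exclusion log has one row per excluded subject with a single reason
    code (MOTION, ARTIFACT or ATTENTION); imaging reasons win when a subject
    fails both an imaging rule and the attention rule.
    """
    roster = _validate(roster)
    motion_fail = roster["mean_abs_motion"] > motion_limit_mm
    artifact_fail = roster["artifact_flag"].astype(bool)
    attention_fail = roster["attention_correct"] < min_attention_correct

    reason = pd.Series(pd.NA, index=roster.index, dtype="object")
    reason[attention_fail] = REASON_ATTENTION
    reason[artifact_fail] = REASON_ARTIFACT     # imaging reasons take precedence
    reason[motion_fail] = REASON_MOTION

    excluded = reason.notna()
    included = roster.loc[~excluded].reset_index(drop=True)
    log = pd.DataFrame({
        "subject": roster.loc[excluded, "subject"].to_numpy(),
        "reason": reason[excluded].to_numpy(),
    })
    return included, log
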