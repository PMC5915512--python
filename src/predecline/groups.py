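"""Biomarker-group classification.

Subjects are classified on amyloid-PET SUVR and CSF p-tau against two
threshold pairs: the standard abnormality thresholds (SUVR > 1.15,
p-tau > 23 pg/ml) and the proposed imminent-decline thresholds
(SUVR > 1.228, p-tau > 45 pg/ml). Primary labels follow the preclinical-AD
criteria: neither biomarker abnormal -> biomarker-negative; exactly one ->
at-risk; both -> preclinical. Within preclinical, ``above_proposed`` marks
subjects with both biomarkers strictly above the proposed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSet",
    "GroupLabel",
    "BIOMARKER_NEGATIVE",
    "AT_RISK",
    "PRECLINICAL",
    "classify_subject",
    "classify_cohort",
    "summarize_groups",
]

BIOMARKER_NEGATIVE = "biomarker-negative"
AT_RISK = "at-risk"
PRECLINICAL = "preclinical"


@dataclass(frozen=True)
class ThresholdSet:
    """Standard abnormality and proposed imminent-decline thresholds."""

    suvr_standard: float = 1.15
    ptau_standard: float = 23.0
    suvr_proposed: float = 1.228
    ptau_proposed: float = 45.0

    def validate(self) -> None:
        if self.suvr_proposed < self.suvr_standard:
            raise ValueError("proposed SUVR threshold below the standard threshold")
        if self.ptau_proposed < self.ptau_standard:
            raise ValueError("proposed p-tau threshold below the standard threshold")


@dataclass(frozen=True)
class GroupLabel:
    primary: str
    above_proposed: bool


def classify_subject(
    suvr: float, ptau: float, thresholds: ThresholdSet | None = None
) -> GroupLabel:
    """Classify one subject; strict ``>`` at every threshold."""
    thr = thresholds or ThresholdSet()
    thr.validate()
    if not (np.isfinite(suvr) and np.isfinite(ptau)):
        raise ValueError(f"nonfinite biomarker values: suvr={suvr}, ptau={ptau}")
    amyloid_pos = suvr > thr.suvr_standard
    tau_pos = ptau > thr.ptau_standard
    if amyloid_pos and tau_pos:
        primary = PRECLINICAL
    elif amyloid_pos or tau_pos:
        primary = AT_RISK
    else:
        primary = BIOMARKER_NEGATIVE
    above = bool(suvr > thr.suvr_proposed and ptau > thr.ptau_proposed)
    return GroupLabel(primary=primary, above_proposed=above)


def classify_cohort(
    cohort: pd.DataFrame, thresholds: ThresholdSet | None = None
) -> pd.DataFrame:
    """Vectorized classification; returns a copy with ``group`` and
    ``above_proposed`` columns appended."""
    thr = thresholds or ThresholdSet()
    thr.validate()
    suvr = cohort["florbetapir_suvr"].to_numpy(dtype=float)
    ptau = cohort["csf_ptau"].to_numpy(dtype=float)
    if not (np.isfinite(suvr).all() and np.isfinite(ptau).all()):
        raise ValueError("nonfinite biomarker values in cohort")
    amyloid_pos = suvr > thr.suvr_standard
    tau_pos = ptau > thr.ptau_standard
    primary = np.where(
        amyloid_pos & tau_pos,
        PRECLINICAL,
        np.where(amyloid_pos | tau_pos, AT_RISK, BIOMARKER_NEGATIVE),
    )
    out = cohort.copy()
    out["group"] = primary
    out["above_proposed"] = (suvr > thr.suvr_proposed) & (ptau > thr.ptau_proposed)
    return out


def summarize_groups(
    cohort: pd.DataFrame, thresholds: ThresholdSet | None = None
) -> dict:
    """Group counts, proportions and the amyloid-positivity rate."""
    thr = thresholds or ThresholdSet()
    labelled = classify_cohort(cohort, thr)
    n = len(labelled)
    counts = {
        label: int((labelled["group"] == label).sum())
        for label in (BIOMARKER_NEGATIVE, AT_RISK, PRECLINICAL)
    }
    amyloid_pos = int(
        (labelled["florbetapir_suvr"] > thr.suvr_standard).sum()
    )
    return {
        "n": n,
        "counts": counts,
        "proportions": {k: (v / n if n else 0.0) for k, v in counts.items()},
        "above_proposed": int(labelled["above_proposed"].sum()),
        "amyloid_positive": amyloid_pos,
        "amyloid_positive_fraction": amyloid_pos / n if n else 0.0,
    }
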