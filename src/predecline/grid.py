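"""Exhaustive two-biomarker threshold grid.

For every pair of candidate thresholds (one candidate per subject and
biomarker, so a 120-subject cohort yields 120 x 120 = 14,400 cells) the
grid evaluates the mean metabolic decline of the group whose amyloid AND
tau biomarkers are both at or above the pair, tests it against zero, and
categorizes the pair relative to the standard and proposed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .groups import ThresholdSet

__all__ = [
    "CATEGORY_BOTH_BELOW",
    "CATEGORY_ONE_ABOVE",
    "CATEGORY_ABOVE_STANDARD",
    "CATEGORY_AT_PROPOSED",
    "ThresholdGridResult",
    "build_threshold_grid",
    "categorize_cell",
]

CATEGORY_BOTH_BELOW = "both-below-standard"
CATEGORY_ONE_ABOVE = "one-above-standard"
CATEGORY_ABOVE_STANDARD = "above-standard-below-proposed"
CATEGORY_AT_PROPOSED = "at-or-above-proposed"


def categorize_cell(
    pair: tuple[float, float], thresholds: ThresholdSet | None = None
) -> str:
    """Category of a threshold pair (amyloid, tau) as in the 3-D grid plot.

    Both at/below standard -> both-below-standard; exactly one above
    standard -> one-above-standard; both above standard with at least one
    below proposed -> above-standard-below-proposed; both at or above the
    proposed thresholds -> at-or-above-proposed.
    """
    thr = thresholds or ThresholdSet()
    amyloid_t, tau_t = pair
    a_std = amyloid_t > thr.suvr_standard
    t_std = tau_t > thr.ptau_standard
    if amyloid_t >= thr.suvr_proposed and tau_t >= thr.ptau_proposed:
        return CATEGORY_AT_PROPOSED
    if a_std and t_std:
        return CATEGORY_ABOVE_STANDARD
    if a_std or t_std:
        return CATEGORY_ONE_ABOVE
    return CATEGORY_BOTH_BELOW


@dataclass
class ThresholdGridResult:
    """Per-cell summaries over the full candidate grid."""

    amyloid_thresholds: np.ndarray
    tau_thresholds: np.ndarray
    group_size: np.ndarray  # (n_amyloid, n_tau) int
    mean_change: np.ndarray  # NaN where group_size < min_cell
    t_stat: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray  # bool, p < alpha
    category: np.ndarray  # object (str)
    min_cell: int
    alpha: float

    @property
    def n_cells(self) -> int:
        return self.group_size.size

    def to_frame(self) -> pd.DataFrame:
        """Long format suitable for 3-D surface plotting."""
        na, nt = self.group_size.shape
        ai, ti = np.meshgrid(np.arange(na), np.arange(nt), indexing="ij")
        return pd.DataFrame(
            {
                "amyloid_t": self.amyloid_thresholds[ai.ravel()],
                "tau_t": self.tau_thresholds[ti.ravel()],
                "group_size": self.group_size.ravel(),
                "mean_change": self.mean_change.ravel(),
                "t_stat": self.t_stat.ravel(),
                "p_value": self.p_value.ravel(),
                "significant": self.significant.ravel(),
                "category": self.category.ravel(),
            }
        )


def build_threshold_grid(
    suvr_values,
    ptau_values,
    change_values,
    thresholds: ThresholdSet | None = None,
    min_cell: int = 3,
    alpha: float = 0.05,
) -> ThresholdGridResult:
    """Evaluate decline in the both-above group over all candidate pairs.

    Candidates per axis are the subjects' observed values (one per
    subject, ties kept), so n subjects yield n x n cells. Per cell the
    group is every subject with suvr >= amyloid candidate AND ptau >= tau
    candidate; the mean change is reported when the group holds at least
    ``min_cell`` subjects, and a two-sided one-sample t-test of the mean
    against zero is run when it holds at least 3.
    """
    thr = thresholds or ThresholdSet()
    suvr = np.asarray(suvr_values, dtype=float)
    ptau = np.asarray(ptau_values, dtype=float)
    q = np.asarray(change_values, dtype=float)
    if not (suvr.shape == ptau.shape == q.shape) or suvr.ndim != 1:
        raise ValueError("suvr, ptau and change arrays must be aligned 1-D")
    n = suvr.size
    if n == 0:
        raise ValueError("empty cohort")
    a_cand = np.sort(suvr)
    t_cand = np.sort(ptau)
    # subject-by-candidate membership indicators
    in_a = suvr[:, None] >= a_cand[None, :]  # (n, n)
    in_t = ptau[:, None] >= t_cand[None, :]
    size = in_a.T.astype(float) @ in_t.astype(float)  # (n_a, n_t)
    sum_q = (in_a * q[:, None]).T @ in_t.astype(float)
    sum_q2 = (in_a * (q**2)[:, None]).T @ in_t.astype(float)
    size_i = size.astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(size_i >= min_cell, sum_q / size, np.nan)
        # unbiased variance of the change within each cell
        var = np.where(
            size_i >= 2, (sum_q2 - size * (sum_q / np.maximum(size, 1)) ** 2)
            / np.maximum(size - 1, 1), np.nan,
        )
        var = np.maximum(var, 0.0)
        testable = (size_i >= 3) & (var > 0)
        tstat = np.where(
            testable,
            (sum_q / np.maximum(size, 1))
            / np.sqrt(var / np.maximum(size, 1)),
            np.nan,
        )
        pval = np.where(
            testable, 2.0 * stats.t.sf(np.abs(tstat), np.maximum(size - 1, 1)), np.nan
        )
    significant = np.where(np.isnan(pval), False, pval < alpha)

    category = np.empty(size.shape, dtype=object)
    a_std = a_cand > thr.suvr_standard
    t_std = t_cand > thr.ptau_standard
    a_prop = a_cand >= thr.suvr_proposed
    t_prop = t_cand >= thr.ptau_proposed
    red = a_prop[:, None] & t_prop[None, :]
    blue = a_std[:, None] & t_std[None, :] & ~red
    yellow = (a_std[:, None] ^ t_std[None, :]) & ~red
    category[:] = CATEGORY_BOTH_BELOW
    category[yellow] = CATEGORY_ONE_ABOVE
    category[blue] = CATEGORY_ABOVE_STANDARD
    category[red] = CATEGORY_AT_PROPOSED

    return ThresholdGridResult(
        amyloid_thresholds=a_cand,
        tau_thresholds=t_cand,
        group_size=size_i,
        mean_change=mean,
        t_stat=tstat,
        p_value=pval,
        significant=significant,
        category=category,
        min_cell=min_cell,
        alpha=alpha,
    )
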