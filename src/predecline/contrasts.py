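"""Covariate-adjusted group contrasts and demographic tables.

Metabolic decline is compared between biomarker groups per ROI with an
ANCOVA (ordinary least squares of the change statistic on group plus
age, sex, education and APOE-e4 carrier status), pairwise group contrasts
Bonferroni-corrected over the declared family of tests. Demographics are
summarized per group with chi-squared tests (no continuity correction)
for categorical fields.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ContrastResult",
    "DEFAULT_COVARIATES",
    "ancova_contrast",
    "contrasts_to_frame",
    "demographics_table",
]

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "education", "apoe4")


@dataclass
class ContrastResult:
    roi: str
    group_a: str
    group_b: str
    adjusted_difference: float  # mean(b) - mean(a), covariate-adjusted
    se: float
    p_raw: float
    p_bonferroni: float
    covariates: tuple[str, ...]


def _formula(covariates: tuple[str, ...]) -> str:
    terms = ["C(group)"]
    for cov in covariates:
        if cov in ("sex",):
            terms.append(f"C({cov})")
        else:
            terms.append(cov)
    return "q_value ~ " + " + ".join(terms)


def ancova_contrast(
    change_table: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    m_tests: int | None = None,
    group_col: str = "group",
) -> list[ContrastResult]:
    """Pairwise covariate-adjusted group differences in decline, per ROI.

    ``cohort`` must carry ``subject_id``, the group column and the
    covariates. The Bonferroni family defaults to (number of ROIs) x
    (number of group pairs) and is declared in every result.
    """
    needed = ["subject_id", group_col, *covariates]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if cohort[list(covariates)].isna().any().any():
        raise ValueError("missing covariate values")
    merged = change_table.merge(
        cohort[needed].rename(columns={group_col: "group"}), on="subject_id"
    )
    groups = sorted(merged["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = merged.groupby(["roi", "group"])["q_value"].size()
    if (counts < 3).any():
        small = counts[counts < 3]
        raise ValueError(f"groups with fewer than 3 subjects: {small.to_dict()}")
    pairs = list(itertools.combinations(groups, 2))
    rois = list(merged["roi"].unique())
    m = m_tests if m_tests is not None else len(rois) * len(pairs)

    results: list[ContrastResult] = []
    formula = _formula(covariates)
    for roi in rois:
        sub = merged[merged["roi"] == roi].copy()
        if "apoe4" in sub.columns:
            sub["apoe4"] = sub["apoe4"].astype(int)
        model = smf.ols(formula, data=sub).fit()
        names = model.params.index
        for ga, gb in pairs:
            # contrast vector for the adjusted difference mean(gb) - mean(ga):
            # group coefficients are offsets from the reference level
            vec = np.zeros(len(names))
            for g, sign in ((gb, 1.0), (ga, -1.0)):
                term = f"C(group)[T.{g}]"
                if term in names:
                    vec[list(names).index(term)] = sign
            test = model.t_test(vec)
            p_raw = float(np.squeeze(test.pvalue))
            results.append(
                ContrastResult(
                    roi=roi,
                    group_a=ga,
                    group_b=gb,
                    adjusted_difference=float(np.squeeze(test.effect)),
                    se=float(np.squeeze(test.sd)),
                    p_raw=p_raw,
                    p_bonferroni=min(1.0, m * p_raw),
                    covariates=tuple(covariates),
                )
            )
    return results


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": r.roi,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "adjusted_difference": r.adjusted_difference,
                "se": r.se,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "covariates": "+".join(r.covariates),
            }
            for r in results
        ]
    )


def demographics_table(
    cohort: pd.DataFrame,
    group_col: str = "group",
    continuous: tuple[str, ...] = (
        "age",
        "education",
        "mmse",
        "csf_ptau",
        "florbetapir_suvr",
        "followup_months",
    ),
    categorical: tuple[str, ...] = ("sex", "apoe4"),
) -> dict:
    """Per-group means/SDs for continuous fields; chi-squared p for
    categorical fields (group x category counts, no continuity correction)."""
    if group_col not in cohort.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = sorted(cohort[group_col].dropna().unique())
    if not groups:
        raise ValueError("no groups present")
    out: dict = {"groups": list(map(str, groups)), "continuous": {}, "categorical": {}}
    for col in continuous:
        if col not in cohort.columns:
            continue
        stats_by_group = {
            str(g): {
                "mean": float(cohort.loc[cohort[group_col] == g, col].mean()),
                "sd": float(cohort.loc[cohort[group_col] == g, col].std(ddof=1)),
                "n": int((cohort[group_col] == g).sum()),
            }
            for g in groups
        }
        out["continuous"][col] = stats_by_group
    for col in categorical:
        if col not in cohort.columns:
            continue
        table = pd.crosstab(cohort[group_col], cohort[col])
        if table.shape[1] == 0 or table.to_numpy().sum() == 0:
            raise ValueError(f"category {col!r} absent in all groups")
        if table.shape[1] == 1 or table.shape[0] == 1:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        out["categorical"][col] = {
            "counts": {str(g): table.loc[g].to_dict() for g in table.index},
            "chi2": float(chi2),
            "p": float(p),
        }
    return out
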