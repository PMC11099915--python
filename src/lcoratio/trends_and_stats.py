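"""Age-trend fitting and the group-comparison statistics of the study.

The qFTAA/hFTAA ratio of plaque cores rises with mouse age in the
overexpressor models (a "plaque-core maturation" transition above ~12
months) while the knock-in model stays flat; the trend is summarised by
an ordinary least-squares third-order polynomial through the per-age
mean ratios.  Group contrasts use ordinary (fixed-effects, unweighted)
one-way ANOVA and the unpaired two-sample t test, with the usual star
bands (*p<0.05, **p<0.01, ***p<0.001, ****p<0.0001).  No
multiple-testing correction is applied anywhere: comparisons are
reported individually, exactly as produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeTrendFit",
    "GroupComparison",
    "fit_age_trend",
    "anova_oneway",
    "ttest_unpaired",
    "genotype_ratio_table",
    "significance_stars",
]


@dataclass(frozen=True)
class AgeTrendFit:
    """Cubic ratio-vs-age fit; coefficients ascending (c0 + c1*a + ...)."""

    coefficients: np.ndarray
    ages: np.ndarray
    mean_ratios: np.ndarray

    def __post_init__(self) -> None:
        if self.coefficients.shape != (4,):
            raise ValueError("cubic fit must have exactly 4 coefficients")

    def predict(self, ages) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(ages, dtype=float),
                                                self.coefficients)


@dataclass(frozen=True)
class GroupComparison:
    """Result of one ANOVA or t test over ratio groups."""

    test_name: str
    labels: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Star band of a p value; 'ns' when p >= 0.05."""
    if np.isnan(p):
        return "ns"
    for threshold, label in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return label
    return "ns"


def fit_age_trend(ages, mean_ratios) -> AgeTrendFit:
    """OLS cubic through (age, mean ratio) points; >= 4 distinct ages."""
    ages = np.asarray(ages, dtype=float)
    mean_ratios = np.asarray(mean_ratios, dtype=float)
    if ages.shape != mean_ratios.shape or ages.ndim != 1:
        raise ValueError("ages and mean_ratios must be equal-length 1-D arrays")
    if np.unique(ages).size < 4:
        raise ValueError("cubic age trend needs >= 4 distinct ages")
    if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(mean_ratios))):
        raise ValueError("ages and means must be finite")
    design = np.vander(ages, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, mean_ratios, rcond=None)
    return AgeTrendFit(coefficients=coeffs, ages=ages, mean_ratios=mean_ratios)


def _group_summary(groups: list[np.ndarray]) -> tuple[tuple, tuple, tuple]:
    n = tuple(int(g.size) for g in groups)
    means = tuple(float(g.mean()) for g in groups)
    sems = tuple(
        float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else 0.0 for g in groups
    )
    return n, means, sems


def anova_oneway(groups, labels: list[str] | None = None) -> GroupComparison:
    """Classical fixed-effects one-way ANOVA over >= 2 groups of n >= 2."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    # All-identical groups: zero between- and within-variance, F := 0.
    if np.isnan(f) and all(np.ptp(a) == 0 for a in arrays):
        f, p = 0.0, 1.0
    n, means, sems = _group_summary(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    return GroupComparison(
        test_name="ordinary one-way ANOVA",
        labels=tuple(labels), n=n, means=means, sems=sems,
        statistic=float(f), p_value=float(p),
    )


def ttest_unpaired(a, b, equal_var: bool = True,
                   labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sample unpaired t test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t) and np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    n, means, sems = _group_summary([a, b])
    name = "unpaired t test" if equal_var else "Welch t test"
    return GroupComparison(
        test_name=name, labels=tuple(labels), n=n, means=means, sems=sems,
        statistic=float(t), p_value=float(p),
    )


def genotype_ratio_table(
    ratio_summaries: pd.DataFrame, ab42_ab40: dict[str, float]
) -> pd.DataFrame:
    """Join per-genotype mean qFTAA/hFTAA ratios with Ab42/Ab40 content.

    ``ratio_summaries`` needs columns genotype, age_class, mean_ratio;
    ``ab42_ab40`` maps genotype -> peptide ratio (user-supplied, from
    external biochemical measurements).  Output is the scatter table
    (one row per genotype x age class); no statistics are computed.
    """
    required = {"genotype", "age_class", "mean_ratio"}
    missing = required - set(ratio_summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    unmatched = set(ratio_summaries["genotype"]) - set(ab42_ab40)
    if unmatched:
        raise KeyError(f"no Ab42/Ab40 value for genotype(s): {sorted(unmatched)}")
    out = ratio_summaries.copy()
    out["ab42_ab40_ratio"] = out["genotype"].map(ab42_ab40)
    return out[["genotype", "age_class", "ab42_ab40_ratio", "mean_ratio"]]
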