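"""Geographic group comparisons, reference-index validation, sensitivity.

Comparisons follow the study design: North (North East, North West,
Yorkshire and The Humber) versus the rest, coastal versus inland (an area
is coastal when more than half its population lives in coastal lower-level
units), the three-class urban-rural spectrum, and the nine regions. Group
differences use two-sample t-tests (pooled by default) and one-way ANOVA.
Validation correlates the composite against a reference deprivation rank
and flags areas whose scores deviate most from a linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index import IndexResult
from .registry import REGIONS, ValidationError

__all__ = [
    "NORTH_REGIONS",
    "GroupComparison",
    "SensitivityReport",
    "ValidationResult",
    "anova_oneway",
    "classify_coastal",
    "classify_north",
    "map_bins",
    "sensitivity_compare",
    "two_group_test",
    "validate_against_reference",
]

NORTH_REGIONS = frozenset({"North East", "North West", "Yorkshire and The Humber"})


@dataclass
class GroupComparison:
    grouping: str
    group_stats: pd.DataFrame  # index: group label; columns: n, mean, sd
    statistic: float
    p_value: float
    test: str  # "t_test" or "anova"

    @property
    def n_total(self) -> int:
        return int(self.group_stats["n"].sum())


def classify_north(region_label: str) -> bool:
    """True for the three northern regions, false for the other six."""
    if region_label not in REGIONS:
        raise ValidationError(f"unknown region {region_label!r}")
    return region_label in NORTH_REGIONS


def classify_coastal(
    lsoa_populations: Sequence[float] | np.ndarray,
    lsoa_coastal_flags: Sequence[bool] | np.ndarray,
) -> bool:
    """Coastal when strictly more than half the population is in coastal units."""
    pops = np.asarray(lsoa_populations, dtype=float)
    flags = np.asarray(lsoa_coastal_flags, dtype=bool)
    if pops.shape != flags.shape or pops.size == 0:
        raise ValidationError("populations and flags must be equal-length, non-empty")
    if np.any(pops < 0):
        raise ValidationError("populations must be non-negative")
    total = pops.sum()
    if total == 0:
        raise ValidationError("total population is zero")
    return bool(pops[flags].sum() / total > 0.5)


def _group_stats(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            label: {
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
            for label, vals in groups.items()
        }
    ).T[["n", "mean", "sd"]]


def two_group_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
    grouping: str = "two_group",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sample t-test, pooled variance by default (Welch optional).

    Degenerate input (both groups constant, equal means) reports t = 0,
    p = 1 rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return GroupComparison(
        grouping=grouping,
        group_stats=_group_stats({labels[0]: a, labels[1]: b}),
        statistic=t,
        p_value=p,
        test="t_test",
    )


def anova_oneway(
    groups: dict[str, Sequence[float]] | Iterable[Sequence[float]],
    grouping: str = "groups",
) -> GroupComparison:
    """One-way ANOVA F-test across two or more groups.

    All-identical values report F = 0, p = 1 (degenerate, not an error).
    """
    if not isinstance(groups, dict):
        groups = {f"g{i + 1}": g for i, g in enumerate(groups)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    total_n = sum(len(v) for v in arrays.values())
    if total_n <= len(arrays):
        raise ValidationError("total observations must exceed the number of groups")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays.values())
        f, p = float(f), float(p)
    return GroupComparison(
        grouping=grouping,
        group_stats=_group_stats(arrays),
        statistic=f,
        p_value=p,
        test="anova",
    )


@dataclass
class ValidationResult:
    pearson_r: float  # Pearson on rank-transformed scores
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    slope: float
    intercept: float
    predicted: pd.Series
    residuals: pd.Series
    top_positive: pd.DataFrame  # actual, predicted, residual
    top_negative: pd.DataFrame


def validate_against_reference(
    cri: pd.Series, reference_rank: pd.Series, n_outliers: int = 10
) -> ValidationResult:
    """Correlate the composite with a reference rank and flag outliers.

    Pearson r is computed on rank-transformed composite scores against the
    reference ranks (Spearman's rho is reported alongside). An ordinary
    least-squares fit of the composite on the reference rank yields
    predicted scores; the largest positive and negative residuals are
    returned as outlier tables.
    """
    common = cri.index.intersection(reference_rank.index)
    if len(common) < 3:
        raise ValidationError("need at least three areas in common")
    if len(common) < len(cri) or len(common) < len(reference_rank):
        raise ValidationError("composite and reference cover different areas")
    y = cri.loc[common].astype(float)
    x = reference_rank.loc[common].astype(float)
    if y.nunique() == 1:
        raise ValidationError("composite is constant; correlation undefined")
    cri_ranked = pd.Series(stats.rankdata(y), index=common)
    pearson_r, pearson_p = stats.pearsonr(cri_ranked, x)
    rho, rho_p = stats.spearmanr(y, x)
    fit = stats.linregress(x, y)
    predicted = pd.Series(fit.intercept + fit.slope * x, index=common, name="predicted")
    residuals = (y - predicted).rename("residual")
    ordered = residuals.sort_values(ascending=False)
    def _tbl(idx):
        return pd.DataFrame(
            {"actual": y.loc[idx], "predicted": predicted.loc[idx], "residual": residuals.loc[idx]}
        )
    return ValidationResult(
        pearson_r=float(pearson_r),
        pearson_p=float(pearson_p),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        predicted=predicted,
        residuals=residuals,
        top_positive=_tbl(ordered.index[:n_outliers]),
        top_negative=_tbl(ordered.index[::-1][:n_outliers]),
    )


@dataclass
class SensitivityReport:
    spearman_rho: float
    spearman_p: float
    region_ranks: pd.DataFrame | None = None  # per-region mean/sd of ranks


def sensitivity_compare(
    weighted: IndexResult,
    unweighted: IndexResult,
    area_regions: pd.Series | None = None,
) -> SensitivityReport:
    """Spearman rank correlation of two composite scores, plus regional ranks.

    Ranks ascend with the score (rank 1 = least resilient), so per-region
    mean ranks compare how each methodology orders the regions.
    """
    a = weighted.cri
    b = unweighted.cri.reindex(a.index)
    if b.isna().any():
        raise ValidationError("indices cover different areas")
    rho, p = stats.spearmanr(a, b)
    region_ranks = None
    if area_regions is not None:
        ranks = pd.DataFrame(
            {
                "weighted_rank": stats.rankdata(a),
                "unweighted_rank": stats.rankdata(b),
            },
            index=a.index,
        )
        ranks["region"] = area_regions.reindex(a.index)
        region_ranks = ranks.groupby("region").agg(["mean", "std"])
    return SensitivityReport(spearman_rho=float(rho), spearman_p=float(p), region_ranks=region_ranks)


#: Bin edges in z-score units and their display labels.
_BIN_EDGES = (-np.inf, -2.0, -1.0, 0.0, 1.0, 2.0, np.inf)
_BIN_LABELS = ("< -2 SD", "-2 to -1 SD", "-1 to 0 SD", "0 to 1 SD", "1 to 2 SD", "> 2 SD")


def map_bins(values: pd.Series) -> pd.Series:
    """Standard-deviations-from-mean bins for choropleth display.

    z-scores are binned at (-inf, -2, -1, 0, 1, 2, inf), each interval
    closed on the left (a value exactly at the mean falls in "0 to 1 SD").
    """
    v = values.astype(float)
    sd = v.std(ddof=1)
    if not sd > 0:
        raise ValidationError("values are constant; bins undefined")
    z = (v - v.mean()) / sd
    idx = np.searchsorted(_BIN_EDGES[1:-1], z.to_numpy(), side="right")
    return pd.Series([_BIN_LABELS[i] for i in idx], index=values.index, name="sd_bin")
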