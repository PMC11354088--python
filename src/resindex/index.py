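"""Indicator weighting, sub-index scores and composite aggregation.

Two aggregation routes are provided. The weighted route groups indicators
by their retained principal component, weights each indicator by its
(normalised) squared loading, forms sub-index scores from the percentile
ranks, scales each sub-index by its component eigenvalue and sums. The
unweighted variant groups indicators by their six thematic domains, takes
plain means, and sums the six sub-indices with no weights.

Sub-index modes:

* ``as_printed`` — SubIndex_i = sum_j(X_ij * W_ij) / n_i (weighted sum
  divided by the member count);
* ``weighted_mean`` — SubIndex_i = sum_j(X_ij * W_ij) with weights
  normalised to sum to one (a true weighted mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factors import SubIndexAssignment
from .preprocess import RankMatrix
from .registry import Registry, ValidationError

__all__ = [
    "IndexResult",
    "WeightScheme",
    "audit_contributions",
    "compute_bric_unweighted",
    "compute_cri",
    "compute_indicator_weights",
    "compute_subindices",
]

SUBINDEX_MODES = ("as_printed", "weighted_mean")
WEIGHT_BASES = ("normalized_squared_loading", "raw_squared_loading")


@dataclass
class WeightScheme:
    """Indicator-level and sub-index-level weights."""

    indicator_weights: pd.Series  # indicator id -> weight
    subindex_weights: pd.Series  # component -> weight
    mode: str = "as_printed"
    weight_basis: str = "normalized_squared_loading"

    def __post_init__(self) -> None:
        if self.mode not in SUBINDEX_MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.weight_basis not in WEIGHT_BASES:
            raise ValidationError(f"unknown weight basis {self.weight_basis!r}")
        if (self.indicator_weights < 0).any() or (self.subindex_weights < 0).any():
            raise ValidationError("weights must be non-negative")


@dataclass
class IndexResult:
    """Per-area sub-index scores, composite score and contribution shares."""

    subindex_raw: pd.DataFrame  # area x component
    subindex_weighted: pd.DataFrame  # area x component
    cri: pd.Series  # per-area composite
    contributions: pd.DataFrame  # area x component shares (rows sum to 1)
    mean_contributions: pd.Series  # per-component share of the composite

    def to_frame(self) -> pd.DataFrame:
        raw = self.subindex_raw.add_prefix("subindex_raw_")
        weighted = self.subindex_weighted.add_prefix("subindex_weighted_")
        contrib = self.contributions.add_prefix("contribution_")
        out = pd.concat([raw, weighted, contrib], axis=1)
        out["cri"] = self.cri
        return out

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="area_id")


def compute_indicator_weights(
    loadings_rotated: pd.DataFrame,
    assignment: SubIndexAssignment,
    weight_basis: str = "normalized_squared_loading",
) -> pd.Series:
    """Squared loading of each indicator on its assigned component.

    Under ``normalized_squared_loading`` the squared loadings are divided by
    their within-sub-index sum, so each sub-index's weights sum to one.
    """
    if weight_basis not in WEIGHT_BASES:
        raise ValidationError(f"unknown weight basis {weight_basis!r}")
    sq = pd.Series(
        {
            ind: float(loadings_rotated.loc[ind].iloc[int(c)] ** 2)
            for ind, c in assignment.component_of.items()
        }
    ).reindex(loadings_rotated.index)
    if weight_basis == "raw_squared_loading":
        return sq.rename("weight")
    out = sq.copy()
    for c, members in assignment.members.items():
        if not members:
            continue
        total = sq.loc[members].sum()
        if total == 0:
            raise ValidationError(f"sub-index {c} has all-zero squared loadings")
        out.loc[members] = sq.loc[members] / total
    return out.rename("weight")


def compute_subindices(
    ranks: RankMatrix,
    assignment: SubIndexAssignment,
    weights: WeightScheme,
) -> pd.DataFrame:
    """Per-area sub-index scores from percentile ranks.

    ``as_printed`` divides the weighted sum by the member count n_i;
    ``weighted_mean`` renormalises the weights within each sub-index and
    takes the weighted sum.
    """
    X = ranks.pct_ranks
    missing = set(assignment.component_of.index) - set(weights.indicator_weights.index)
    if missing:
        raise ValidationError(f"weights missing for indicators: {sorted(missing)}")
    cols = {}
    for c in sorted(assignment.members):
        members = assignment.members[c]
        if not members:
            raise ValidationError(f"sub-index {c} has no indicators")
        w = weights.indicator_weights.loc[members]
        if weights.mode == "weighted_mean":
            total = w.sum()
            if total == 0:
                raise ValidationError(f"sub-index {c} has zero total weight")
            cols[c] = X[members].to_numpy() @ (w / total).to_numpy()
        else:  # as_printed
            cols[c] = (X[members].to_numpy() @ w.to_numpy()) / len(members)
    return pd.DataFrame(cols, index=X.index)


def compute_cri(
    subindex_raw: pd.DataFrame, subindex_weights: pd.Series
) -> IndexResult:
    """Scale sub-indices by their weights and sum into the composite.

    Contributions are each weighted sub-index's share of the per-area
    composite; rows with a zero composite get NaN shares.
    """
    if (subindex_weights < 0).any():
        raise ValidationError("sub-index weights must be non-negative")
    w = subindex_weights.reindex(subindex_raw.columns)
    if w.isna().any():
        raise ValidationError(
            f"missing sub-index weights for components {w.index[w.isna()].tolist()}"
        )
    weighted = subindex_raw * w
    cri = weighted.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        contributions = weighted.div(cri.where(cri != 0), axis=0)
    mean_contributions = contributions.mean(axis=0, skipna=True)
    return IndexResult(
        subindex_raw=subindex_raw,
        subindex_weighted=weighted,
        cri=cri,
        contributions=contributions,
        mean_contributions=mean_contributions,
    )


def compute_bric_unweighted(ranks: RankMatrix, registry: Registry) -> IndexResult:
    """Unweighted domain-grouped variant: six plain-mean sub-indices, summed."""
    X = ranks.pct_ranks
    members = registry.domain_members()
    empty = [d for d, m in members.items() if not m]
    if empty:
        raise ValidationError(f"domains with no indicators: {empty}")
    cols = {d: X[m].mean(axis=1) for d, m in members.items()}
    subindex = pd.DataFrame(cols, index=X.index)
    weights = pd.Series(1.0, index=subindex.columns)
    result = compute_cri(subindex, weights)
    return result


def audit_contributions(result: IndexResult) -> pd.Series:
    """Mean per-area contribution share of each sub-index, as percentages.

    Areas with a non-positive composite are excluded with a warning via the
    NaN handling in :func:`compute_cri`.
    """
    shares = result.contributions.dropna(how="any")
    return (shares.mean(axis=0) * 100.0).rename("mean_contribution_pct")
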