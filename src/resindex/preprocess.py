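"""Imputation, standardisation and direction-aligned percentile ranking.

Imputation implements the three deterministic fill rules used on the real
data: broadcasting upper-tier per-capita values to constituent areas,
substituting the previous year's value, and the peer-group mean. Each fill
is logged. Standardisation (z-scores, sample sd) feeds the PCA stage;
percentile ranks (Hazen convention by default) feed index aggregation, with
the ranking reversed for indicators where a lower raw value is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .registry import AreaTable, ValidationError

__all__ = [
    "ImputationLog",
    "RankMatrix",
    "StandardizedMatrix",
    "impute_from_upper_tier",
    "impute_peer_group",
    "impute_prior_year",
    "percentile_rank",
    "population_weighted_mean",
    "standardize",
]


@dataclass
class ImputationLog:
    """Record of every filled cell (area, indicator, method, value)."""

    records: list[dict] = field(default_factory=list)

    def add(self, area_id: str, indicator_id: str, method: str, value: float) -> None:
        self.records.append(
            {
                "area_id": area_id,
                "indicator_id": indicator_id,
                "method": method,
                "value": value,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["area_id", "indicator_id", "method", "value"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


def population_weighted_mean(
    values: Sequence[float] | np.ndarray, weights: Sequence[float] | np.ndarray
) -> float:
    """Population-weighted mean: sum(v * w) / sum(w)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValidationError("values and weights must have the same length")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValidationError("at least one weight must be positive")
    if np.any(~np.isfinite(v)):
        raise ValidationError("values must not contain missing entries")
    return float(np.sum(v * w) / np.sum(w))


def impute_from_upper_tier(
    column: pd.Series,
    upper_values: Mapping[str, float] | pd.Series,
    mapping: Mapping[str, str] | pd.Series,
    log: ImputationLog | None = None,
    indicator_id: str = "",
) -> pd.Series:
    """Fill gaps by broadcasting each area's upper-tier per-capita value.

    Observed cells are never touched. Raises if a gap area has no mapped
    upper-tier value.
    """
    out = column.copy()
    upper = pd.Series(upper_values, dtype=float)
    for aid in column.index[column.isna()]:
        ut = mapping[aid] if not isinstance(mapping, pd.Series) else mapping.loc[aid]
        if ut is None or (isinstance(ut, float) and np.isnan(ut)) or ut not in upper.index:
            raise ValidationError(
                f"area {aid!r} has a gap but no mapped upper-tier value"
            )
        filled = float(upper.loc[ut])
        out.loc[aid] = filled
        if log is not None:
            log.add(str(aid), indicator_id or str(column.name), "upper_tier", filled)
    return out


def impute_prior_year(
    column: pd.Series,
    prior: pd.Series,
    log: ImputationLog | None = None,
    indicator_id: str = "",
) -> pd.Series:
    """Fill gaps with the previous year's value for the same area."""
    out = column.copy()
    for aid in column.index[column.isna()]:
        if aid not in prior.index or pd.isna(prior.loc[aid]):
            raise ValidationError(
                f"area {aid!r} missing in both the current and prior year"
            )
        filled = float(prior.loc[aid])
        out.loc[aid] = filled
        if log is not None:
            log.add(str(aid), indicator_id or str(column.name), "prior_year", filled)
    return out


def impute_peer_group(
    column: pd.Series,
    peer_groups: Mapping[str, Sequence[str]],
    log: ImputationLog | None = None,
    indicator_id: str = "",
) -> pd.Series:
    """Fill gaps with the mean of observed values among the area's peers.

    ``peer_groups`` maps each gap area to its peer members; the gap area
    itself is excluded from the mean. Raises if no peer has an observed
    value.
    """
    out = column.copy()
    for aid in column.index[column.isna()]:
        if aid not in peer_groups:
            raise ValidationError(f"area {aid!r} has a gap but no peer group")
        peers = [p for p in peer_groups[aid] if p != aid]
        observed = column.loc[[p for p in peers if p in column.index]].dropna()
        if observed.empty:
            raise ValidationError(
                f"peer group for area {aid!r} has no observed values"
            )
        filled = float(observed.mean())
        out.loc[aid] = filled
        if log is not None:
            log.add(str(aid), indicator_id or str(column.name), "peer_group", filled)
    return out


@dataclass
class StandardizedMatrix:
    """Column-wise z-scores with the moments used to compute them."""

    z_values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series

    @property
    def n_obs(self) -> int:
        return self.z_values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.z_values.shape[1]


def standardize(table: AreaTable | pd.DataFrame) -> StandardizedMatrix:
    """z = (x - column mean) / column sd, sample sd (n-1 denominator).

    Requires a complete matrix; a constant column is an error naming the
    indicator.
    """
    frame = table.values if isinstance(table, AreaTable) else table
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValidationError(f"missing values remain in columns {bad}; impute first")
    means = frame.mean()
    sds = frame.std(ddof=1)
    zero = sds[sds == 0]
    if not zero.empty:
        raise ValidationError(f"constant column(s): {zero.index.tolist()}")
    return StandardizedMatrix((frame - means) / sds, means, sds)


@dataclass
class RankMatrix:
    """Direction-aligned percentile ranks in [0, 100]; higher = more favourable."""

    pct_ranks: pd.DataFrame
    convention: str = "hazen"


def _percentile_column(x: np.ndarray, convention: str) -> np.ndarray:
    r = rankdata(x, method="average")
    n = len(x)
    if convention == "hazen":
        return 100.0 * (r - 0.5) / n
    if convention == "weibull":
        return 100.0 * r / (n + 1)
    if convention == "plain":
        return 100.0 * r / n
    raise ValidationError(f"unknown percentile convention {convention!r}")


def percentile_rank(
    table: AreaTable, convention: str = "hazen"
) -> RankMatrix:
    """Per-indicator percentile ranks, reversed for LOW_GOOD indicators.

    Each column is ranked ascending in its resilience-favourable direction
    (raw values for HIGH_GOOD, negated for LOW_GOOD), ties averaged. Under
    the default Hazen convention percentile = 100 * (rank - 0.5) / N, so a
    tie-free column has mean exactly 50.
    """
    frame = table.values
    if frame.isna().any().any():
        raise ValidationError("missing values remain; impute before ranking")
    out = {}
    for ind in table.registry:
        col = frame[ind.id].to_numpy(dtype=float)
        aligned = col if ind.high_good else -col
        out[ind.id] = _percentile_column(aligned, convention)
    ranks = pd.DataFrame(out, index=frame.index)[table.registry.ids]
    return RankMatrix(ranks, convention)
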