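"""Seeded synthetic area-by-indicator data with a known latent-factor truth.

Generates tables shaped like the real study data: a configurable number of
areas and indicators, a block latent-factor structure, mixed indicator
directions, region/coastal/rurality metadata, nested lower-level geography,
and a reference deprivation index built to be negatively correlated with
latent resilience. Every downstream stage of the pipeline can therefore be
tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .registry import (
    BRIC_DOMAINS,
    REGIONS,
    RURALITY_CLASSES,
    AreaMeta,
    AreaTable,
    IndicatorMeta,
    Registry,
    ValidationError,
    load_bundled_registry,
)

__all__ = [
    "MISSINGNESS_PATTERNS",
    "MissingnessInjection",
    "SyntheticConfig",
    "SyntheticResult",
    "SyntheticTruth",
    "generate",
    "inject_missingness",
]

MISSINGNESS_PATTERNS = ("upper_tier_only", "prior_year_gap", "peer_group_gap")

#: Urban / mixed / rural shares, roughly matching English district counts.
_RURALITY_FRACTIONS = (0.57, 0.16, 0.27)


@dataclass(frozen=True)
class SyntheticConfig:
    n_areas: int = 307
    n_indicators: int = 44
    n_factors: int = 5
    loading_primary: float = 0.7
    loading_cross: float = 0.1
    noise_sd: float | None = None  # None -> chosen so indicators have unit variance
    low_good_fraction: float = 0.5
    n_regions: int = 9
    coastal_fraction: float = 0.2
    lsoas_per_area: int = 10
    areas_per_upper_tier: int = 4
    peer_group_size: int = 8
    median_population: float = 142_000.0
    population_log_sd: float = 0.55
    deprivation_factor_weights: tuple[float, ...] | None = None  # None -> all ones
    deprivation_noise_sd: float = 1.0
    use_bundled_registry: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors > self.n_indicators:
            raise ValidationError("n_factors cannot exceed n_indicators")
        if self.n_factors < 1 or self.n_areas < 2:
            raise ValidationError("need at least one factor and two areas")
        for frac in (self.low_good_fraction, self.coastal_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.deprivation_noise_sd <= 0:
            raise ValidationError("deprivation_noise_sd must be positive")
        if self.deprivation_factor_weights is not None and len(
            self.deprivation_factor_weights
        ) != self.n_factors:
            raise ValidationError(
                "deprivation_factor_weights length must equal n_factors"
            )

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        var = (
            1.0
            - self.loading_primary**2
            - (self.n_factors - 1) * self.loading_cross**2
        )
        if var <= 0:
            raise ValidationError(
                "loadings imply non-positive noise variance; set noise_sd explicitly"
            )
        return float(np.sqrt(var))

    @property
    def resolved_deprivation_weights(self) -> np.ndarray:
        if self.deprivation_factor_weights is None:
            return np.ones(self.n_factors)
        return np.asarray(self.deprivation_factor_weights, dtype=float)


@dataclass
class SyntheticTruth:
    """Generating quantities retained for recovery testing."""

    factor_scores: np.ndarray  # areas x factors
    loading_matrix: np.ndarray  # indicators x factors
    block_assignment: np.ndarray  # indicator -> factor index
    latent_resilience: np.ndarray  # per-area equal-weight factor sum
    true_directions: list[str]

    def write(self, path: str | Path, indicator_ids: list[str]) -> None:
        pd.DataFrame(
            {
                "indicator_id": indicator_ids,
                "block": self.block_assignment,
                "direction": self.true_directions,
            }
        ).to_csv(path, index=False)


@dataclass
class SyntheticResult:
    table: AreaTable
    truth: SyntheticTruth
    reference: pd.DataFrame  # area_id-indexed; columns: deprivation_score, imd_rank
    lsoas: pd.DataFrame  # lsoa_id, area_id, population, coastal


def _synthetic_registry(config: SyntheticConfig, rng: np.random.Generator) -> Registry:
    n = config.n_indicators
    n_low = int(round(config.low_good_fraction * n))
    low_idx = set(rng.choice(n, size=n_low, replace=False).tolist())
    indicators = tuple(
        IndicatorMeta(
            id=f"ind_{j + 1:03d}",
            name=f"synthetic indicator {j + 1}",
            theme="Other",
            bric_domain=BRIC_DOMAINS[j % len(BRIC_DOMAINS)],
            direction="LOW_GOOD" if j in low_idx else "HIGH_GOOD",
        )
        for j in range(n)
    )
    return Registry(indicators)


def _block_assignment(n_indicators: int, n_factors: int) -> np.ndarray:
    """Contiguous blocks with sizes differing by at most one."""
    blocks = np.array_split(np.arange(n_indicators), n_factors)
    assignment = np.empty(n_indicators, dtype=int)
    for f, idx in enumerate(blocks):
        assignment[idx] = f
    return assignment


def _area_metadata(config: SyntheticConfig, rng: np.random.Generator) -> tuple[AreaMeta, ...]:
    n = config.n_areas
    regions = [REGIONS[i % config.n_regions] for i in range(n)]
    n_coastal = int(round(config.coastal_fraction * n))
    coastal_ids = set(rng.choice(n, size=n_coastal, replace=False).tolist())
    # deterministic rurality mix by cumulative shares over a shuffled order
    order = rng.permutation(n)
    bounds = np.cumsum(np.round(np.array(_RURALITY_FRACTIONS) * n).astype(int))
    rurality = np.empty(n, dtype=object)
    prev = 0
    for cls, hi in zip(RURALITY_CLASSES, bounds):
        rurality[order[prev:hi]] = cls
        prev = hi
    rurality[order[bounds[-1]:]] = RURALITY_CLASSES[-1]
    populations = rng.lognormal(
        mean=np.log(config.median_population), sigma=config.population_log_sd, size=n
    )
    return tuple(
        AreaMeta(
            area_id=f"A{i + 1:03d}",
            name=f"Area {i + 1}",
            region=regions[i],
            coastal=i in coastal_ids,
            rurality=str(rurality[i]),
            population=float(populations[i]),
            upper_tier_id=f"UT{i // config.areas_per_upper_tier + 1:03d}",
            peer_group=f"PG{i // config.peer_group_size + 1:03d}",
        )
        for i in range(n)
    )


def _lsoa_table(
    areas: tuple[AreaMeta, ...], config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Nested lower-level geography consistent with each area's coastal flag."""
    rows = []
    for area in areas:
        shares = rng.dirichlet(np.full(config.lsoas_per_area, 5.0))
        pops = shares * area.population
        flags = np.zeros(config.lsoas_per_area, dtype=bool)
        if area.coastal:
            # flag largest LSOAs until the coastal population share exceeds half
            order = np.argsort(pops)[::-1]
            total, acc = pops.sum(), 0.0
            for k in order:
                flags[k] = True
                acc += pops[k]
                if acc > 0.5 * total:
                    break
        elif config.lsoas_per_area > 1:
            flags[int(np.argmin(pops))] = True  # a minority coastal fringe
        for m in range(config.lsoas_per_area):
            rows.append(
                {
                    "lsoa_id": f"{area.area_id}L{m + 1:02d}",
                    "area_id": area.area_id,
                    "population": float(pops[m]),
                    "coastal": bool(flags[m]),
                }
            )
    return pd.DataFrame(rows)


def generate(config: SyntheticConfig | None = None) -> SyntheticResult:
    """Generate a seeded synthetic dataset with known factor structure.

    Indicator values are ``factor_scores @ loadings.T`` plus Gaussian noise;
    columns whose registry direction is ``LOW_GOOD`` are negated afterwards,
    so the favourable direction matches the metadata. The reference index is
    the rank of a noisy negative-weighted combination of the factor scores
    (higher rank = more deprived), which makes it negatively correlated with
    latent resilience by construction.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    if config.use_bundled_registry and config.n_indicators == 44:
        registry = load_bundled_registry()
    else:
        registry = _synthetic_registry(config, rng)

    n, p, k = config.n_areas, config.n_indicators, config.n_factors
    block = _block_assignment(p, k)
    loadings = np.full((p, k), config.loading_cross)
    loadings[np.arange(p), block] = config.loading_primary

    factor_scores = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p)) * config.resolved_noise_sd
    values = factor_scores @ loadings.T + noise

    directions = [ind.direction for ind in registry]
    flip = np.array([d == "LOW_GOOD" for d in directions])
    values[:, flip] *= -1.0

    areas = _area_metadata(config, rng)
    frame = pd.DataFrame(
        values, index=[a.area_id for a in areas], columns=registry.ids
    )
    frame.index.name = "area_id"
    table = AreaTable(areas, frame, registry)

    truth = SyntheticTruth(
        factor_scores=factor_scores,
        loading_matrix=loadings,
        block_assignment=block,
        latent_resilience=factor_scores.sum(axis=1),
        true_directions=directions,
    )

    dep_score = -factor_scores @ config.resolved_deprivation_weights
    dep_score = dep_score + rng.standard_normal(n) * config.deprivation_noise_sd
    reference = pd.DataFrame(
        {
            "deprivation_score": dep_score,
            "imd_rank": rankdata(dep_score).astype(int),
        },
        index=frame.index,
    )

    lsoas = _lsoa_table(areas, config, rng)
    return SyntheticResult(table=table, truth=truth, reference=reference, lsoas=lsoas)


@dataclass
class MissingnessInjection:
    """A blanked copy of a table plus the manifest of removed cells.

    ``aux`` carries the companion data needed to impute the gaps back:
    an upper-tier value table for ``upper_tier_only``, a prior-year column
    for ``prior_year_gap``; ``peer_group_gap`` needs none.
    """

    table: AreaTable
    manifest: pd.DataFrame  # columns: area_id, indicator_id, pattern
    aux: dict[str, pd.Series | pd.DataFrame] = field(default_factory=dict)


def inject_missingness(
    table: AreaTable,
    pattern: str,
    seed: int = 0,
    n_indicators: int | None = None,
    n_areas: int | None = None,
) -> MissingnessInjection:
    """Blank cells following one of the three observed missingness patterns.

    * ``upper_tier_only`` — whole columns blanked (default 2 indicators);
      emits a per-upper-tier companion table of population-weighted means.
    * ``prior_year_gap`` — a few areas blanked in one column (default 3);
      emits a complete prior-year column for that indicator.
    * ``peer_group_gap`` — a few areas blanked in one column (default 2).
    """
    if pattern not in MISSINGNESS_PATTERNS:
        raise ValidationError(
            f"unknown missingness pattern {pattern!r}; expected one of "
            f"{MISSINGNESS_PATTERNS}"
        )
    rng = np.random.default_rng(seed)
    out = table.copy()
    values = out.values
    meta = table.area_meta_frame()
    records: list[dict[str, str]] = []
    aux: dict[str, pd.Series | pd.DataFrame] = {}

    if pattern == "upper_tier_only":
        n_ind = 2 if n_indicators is None else n_indicators
        cols = rng.choice(table.registry.ids, size=n_ind, replace=False)
        upper_rows = {}
        for col in cols:
            pops = meta["population"]
            grouped = values[col].groupby(meta["upper_tier_id"])
            weighted = {
                ut: float(np.average(sub, weights=pops.loc[sub.index]))
                for ut, sub in grouped
            }
            upper_rows[col] = weighted
            records += [
                {"area_id": aid, "indicator_id": col, "pattern": pattern}
                for aid in values.index
            ]
            values[col] = np.nan
        aux["upper_values"] = pd.DataFrame(upper_rows)
        aux["upper_values"].index.name = "upper_tier_id"
    else:
        n_gap = (3 if pattern == "prior_year_gap" else 2) if n_areas is None else n_areas
        col = str(rng.choice(table.registry.ids))
        gap_areas = rng.choice(values.index.to_numpy(), size=n_gap, replace=False)
        if pattern == "prior_year_gap":
            prior = values[col] + rng.standard_normal(len(values)) * 0.05
            prior.name = col
            aux["prior"] = prior
        for aid in gap_areas:
            values.loc[aid, col] = np.nan
            records.append({"area_id": str(aid), "indicator_id": col, "pattern": pattern})

    manifest = pd.DataFrame(records, columns=["area_id", "indicator_id", "pattern"])
    return MissingnessInjection(table=out, manifest=manifest, aux=aux)
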