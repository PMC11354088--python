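"""End-to-end pipeline: impute, test, decompose, weight, aggregate, compare.

`run_pipeline` executes the construction sequence on an in-memory
:class:`~resindex.registry.AreaTable` and returns every intermediate
artifact; `run_pipeline_files` is the path-based wrapper used by the CLI
and also writes all report CSVs plus a JSON run manifest.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    GroupComparison,
    SensitivityReport,
    ValidationResult,
    anova_oneway,
    classify_north,
    map_bins,
    sensitivity_compare,
    two_group_test,
    validate_against_reference,
)
from .factors import (
    FactorModelResult,
    SubIndexAssignment,
    assign_to_subindices,
    fit_factor_model,
)
from .index import (
    SUBINDEX_MODES,
    WEIGHT_BASES,
    IndexResult,
    WeightScheme,
    audit_contributions,
    compute_bric_unweighted,
    compute_cri,
    compute_indicator_weights,
    compute_subindices,
)
from .preprocess import (
    ImputationLog,
    RankMatrix,
    impute_from_upper_tier,
    impute_peer_group,
    impute_prior_year,
    percentile_rank,
    standardize,
)
from .registry import AreaTable, Registry, ValidationError, load_registry
from .synthetic import MissingnessInjection

__all__ = ["PipelineConfig", "PipelineResult", "attach_bins_to_geojson", "run_pipeline", "run_pipeline_files"]

_PERCENTILE_CONVENTIONS = ("hazen", "weibull", "plain")


@dataclass
class PipelineConfig:
    """All knobs of the construction pipeline, YAML-loadable."""

    percentile_convention: str = "hazen"
    kaiser_normalize: bool = False
    pa_reps: int = 1000
    pa_quantile: float | None = None  # None -> mean random eigenvalues
    rotate_all: bool = False
    seed: int = 0
    weight_mode: str = "as_printed"
    weight_basis: str = "normalized_squared_loading"
    subindex_weight_source: str = "eigenvalues"  # or "rotated_ssq"
    welch: bool = False
    n_outliers: int = 10
    excluded_areas: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.percentile_convention not in _PERCENTILE_CONVENTIONS:
            raise ValidationError(
                f"unknown percentile convention {self.percentile_convention!r}"
            )
        if self.weight_mode not in SUBINDEX_MODES:
            raise ValidationError(f"unknown weight mode {self.weight_mode!r}")
        if self.weight_basis not in WEIGHT_BASES:
            raise ValidationError(f"unknown weight basis {self.weight_basis!r}")
        if self.subindex_weight_source not in ("eigenvalues", "rotated_ssq"):
            raise ValidationError(
                f"unknown sub-index weight source {self.subindex_weight_source!r}"
            )
        if self.pa_reps < 1:
            raise ValidationError("pa_reps must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "excluded_areas" in raw and raw["excluded_areas"] is not None:
            raw["excluded_areas"] = tuple(raw["excluded_areas"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_areas"] = list(d["excluded_areas"])
        return d


@dataclass
class PipelineResult:
    table: AreaTable
    imputation_log: ImputationLog
    factor_model: FactorModelResult
    assignment: SubIndexAssignment
    weights: WeightScheme
    ranks: RankMatrix
    weighted: IndexResult
    unweighted: IndexResult
    mean_contributions_pct: pd.Series
    comparisons: dict[str, GroupComparison]
    sensitivity: SensitivityReport
    validation: ValidationResult | None
    bins: pd.Series
    manifest: dict


def _apply_imputations(
    table: AreaTable, injection: MissingnessInjection, log: ImputationLog
) -> AreaTable:
    """Fill the gaps recorded in a missingness manifest using its aux data."""
    out = table.copy()
    meta = table.area_meta_frame()
    peer_map = {
        aid: meta.index[meta["peer_group"] == meta.loc[aid, "peer_group"]].tolist()
        for aid in meta.index
    }
    for col in injection.manifest["indicator_id"].unique():
        pattern = injection.manifest.loc[
            injection.manifest["indicator_id"] == col, "pattern"
        ].iloc[0]
        if pattern == "upper_tier_only":
            out.values[col] = impute_from_upper_tier(
                out.values[col],
                injection.aux["upper_values"][col],
                meta["upper_tier_id"],
                log=log,
                indicator_id=col,
            )
        elif pattern == "prior_year_gap":
            out.values[col] = impute_prior_year(
                out.values[col], injection.aux["prior"], log=log, indicator_id=col
            )
        elif pattern == "peer_group_gap":
            out.values[col] = impute_peer_group(
                out.values[col], peer_map, log=log, indicator_id=col
            )
    return out


def _geo_comparisons(
    cri: pd.Series, meta: pd.DataFrame, config: PipelineConfig
) -> dict[str, GroupComparison]:
    comparisons: dict[str, GroupComparison] = {}
    region_groups = {
        r: cri.loc[meta.index[meta["region"] == r]].to_numpy()
        for r in sorted(meta["region"].unique())
    }
    comparisons["region"] = anova_oneway(region_groups, grouping="region")
    north = meta["region"].map(classify_north)
    comparisons["north_south"] = two_group_test(
        cri.loc[meta.index[~north]],
        cri.loc[meta.index[north]],
        welch=config.welch,
        grouping="north_south",
        labels=("midlands_and_south", "north"),
    )
    comparisons["coastal_inland"] = two_group_test(
        cri.loc[meta.index[~meta["coastal"]]],
        cri.loc[meta.index[meta["coastal"]]],
        welch=config.welch,
        grouping="coastal_inland",
        labels=("inland", "coastal"),
    )
    rur_groups = {
        r: cri.loc[meta.index[meta["rurality"] == r]].to_numpy()
        for r in sorted(meta["rurality"].unique())
    }
    comparisons["urban_rural"] = anova_oneway(rur_groups, grouping="urban_rural")
    return comparisons


def run_pipeline(
    table: AreaTable,
    config: PipelineConfig | None = None,
    reference_rank: pd.Series | None = None,
    injection: MissingnessInjection | None = None,
) -> PipelineResult:
    """Execute the full construction sequence on an area table."""
    config = config or PipelineConfig()
    stages: list[str] = []

    if config.excluded_areas:
        from .registry import apply_exclusions

        table = apply_exclusions(table, list(config.excluded_areas), strict=False)
        stages.append(f"exclusions: {len(config.excluded_areas)} requested")

    log = ImputationLog()
    if injection is not None:
        table = _apply_imputations(table, injection, log)
    stages.append(f"imputation: {len(log)} cells filled")

    z = standardize(table)
    stages.append(f"standardize: {z.n_obs} areas x {z.n_vars} indicators")

    model = fit_factor_model(
        z.z_values,
        n_reps=config.pa_reps,
        seed=config.seed,
        quantile=config.pa_quantile,
        kaiser_normalize=config.kaiser_normalize,
        rotate_all=config.rotate_all,
    )
    assert model.suitability is not None
    stages.append(
        f"suitability: KMO={model.suitability.kmo:.3f} "
        f"Bartlett chi2={model.suitability.bartlett_chi2:.1f} "
        f"p={model.suitability.bartlett_p:.2e}"
    )
    if model.k_retained is None or model.k_retained < 1:
        raise ValidationError("parallel analysis retained no components")
    stages.append(f"parallel analysis: k_retained={model.k_retained}")

    assert model.loadings_rotated is not None
    assignment = assign_to_subindices(model.loadings_rotated)
    indicator_weights = compute_indicator_weights(
        model.loadings_rotated, assignment, weight_basis=config.weight_basis
    )
    if config.subindex_weight_source == "eigenvalues":
        sub_w = pd.Series(
            model.eigenvalues[: model.k_retained],
            index=sorted(assignment.members),
        )
    else:
        ssq = (model.loadings_rotated**2).sum(axis=0)
        sub_w = pd.Series(ssq.to_numpy(), index=sorted(assignment.members))
    weights = WeightScheme(
        indicator_weights=indicator_weights,
        subindex_weights=sub_w,
        mode=config.weight_mode,
        weight_basis=config.weight_basis,
    )

    ranks = percentile_rank(table, convention=config.percentile_convention)
    subindex_raw = compute_subindices(ranks, assignment, weights)
    weighted = compute_cri(subindex_raw, weights.subindex_weights)
    unweighted = compute_bric_unweighted(ranks, table.registry)
    mean_contrib = audit_contributions(weighted)
    stages.append(
        "aggregate: mean CRI "
        f"{weighted.cri.mean():.2f} (sd {weighted.cri.std(ddof=1):.2f})"
    )

    meta = table.area_meta_frame()
    comparisons = _geo_comparisons(weighted.cri, meta, config)
    sensitivity = sensitivity_compare(weighted, unweighted, meta["region"])
    stages.append(f"sensitivity: spearman rho={sensitivity.spearman_rho:.3f}")

    validation = None
    if reference_rank is not None:
        validation = validate_against_reference(
            weighted.cri,
            reference_rank.reindex(weighted.cri.index),
            n_outliers=config.n_outliers,
        )
        stages.append(f"validation: pearson r={validation.pearson_r:.3f}")

    bins = map_bins(weighted.cri)

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_areas": table.n_areas,
        "n_indicators": table.n_indicators,
        "k_retained": model.k_retained,
        "kmo": model.suitability.kmo,
        "bartlett_p": model.suitability.bartlett_p,
        "stages": stages,
    }
    return PipelineResult(
        table=table,
        imputation_log=log,
        factor_model=model,
        assignment=assignment,
        weights=weights,
        ranks=ranks,
        weighted=weighted,
        unweighted=unweighted,
        mean_contributions_pct=mean_contrib,
        comparisons=comparisons,
        sensitivity=sensitivity,
        validation=validation,
        bins=bins,
        manifest=manifest,
    )


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    model = result.factor_model
    pd.DataFrame(
        {
            "eigenvalue": model.eigenvalues,
            "variance_explained_pct": 100.0 * model.variance_explained,
            "random_eigenvalue_mean": model.random_eigenvalue_means,
            "adjusted_eigenvalue": model.adjusted_eigenvalues,
        }
    ).to_csv(outdir / "eigenvalues.csv", index_label="component")
    model.loadings_unrotated.to_csv(outdir / "loadings_unrotated.csv", index_label="indicator_id")
    if model.loadings_rotated is not None:
        model.loadings_rotated.to_csv(outdir / "loadings_rotated.csv", index_label="indicator_id")
    pd.DataFrame(
        {
            "component": result.assignment.component_of,
            "weight": result.weights.indicator_weights,
        }
    ).to_csv(outdir / "indicator_weights.csv", index_label="indicator_id")
    result.weights.subindex_weights.rename("weight").to_csv(
        outdir / "subindex_weights.csv", index_label="component"
    )
    result.ranks.pct_ranks.to_csv(outdir / "percentile_ranks.csv", index_label="area_id")
    result.weighted.write(outdir / "index_weighted.csv")
    result.unweighted.write(outdir / "index_unweighted.csv")
    result.mean_contributions_pct.to_csv(outdir / "mean_contributions.csv", index_label="component")
    result.imputation_log.write(outdir / "imputation_log.csv")
    rows = []
    for name, comp in result.comparisons.items():
        for label, st in comp.group_stats.iterrows():
            rows.append(
                {
                    "grouping": name,
                    "group": label,
                    "n": int(st["n"]),
                    "mean": st["mean"],
                    "sd": st["sd"],
                    "test": comp.test,
                    "statistic": comp.statistic,
                    "p_value": comp.p_value,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "geo_comparisons.csv", index=False)
    if result.validation is not None:
        v = result.validation
        pd.DataFrame(
            {
                "metric": ["pearson_r_on_ranks", "pearson_p", "spearman_rho", "spearman_p", "slope", "intercept"],
                "value": [v.pearson_r, v.pearson_p, v.spearman_rho, v.spearman_p, v.slope, v.intercept],
            }
        ).to_csv(outdir / "validation.csv", index=False)
        v.top_positive.to_csv(outdir / "outliers_positive.csv", index_label="area_id")
        v.top_negative.to_csv(outdir / "outliers_negative.csv", index_label="area_id")
    result.bins.to_csv(outdir / "map_bins.csv", index_label="area_id")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def run_pipeline_files(
    values_path: str | Path,
    registry_path: str | Path,
    outdir: str | Path,
    meta_path: str | Path | None = None,
    reference_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Path-based pipeline entry point; writes all report CSVs to ``outdir``."""
    registry = load_registry(registry_path)
    table = AreaTable.read(values_path, registry, meta_path=meta_path)
    reference = None
    if reference_path is not None:
        ref = pd.read_csv(reference_path, index_col="area_id")
        ref.index = ref.index.astype(str)
        reference = ref["imd_rank"]
    result = run_pipeline(table, config=config, reference_rank=reference)
    _write_outputs(result, Path(outdir))
    return result


def attach_bins_to_geojson(geojson: dict, bins: pd.Series, key: str = "area_id") -> dict:
    """Attach SD-bin labels as a ``sd_bin`` property on matching features."""
    out = json.loads(json.dumps(geojson))  # deep copy
    for feature in out.get("features", []):
        aid = feature.get("properties", {}).get(key)
        if aid in bins.index:
            feature["properties"]["sd_bin"] = str(bins.loc[aid])
    return out
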