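# resindex

Construction toolkit for PCA-weighted composite resilience indices over
area-level indicator tables.

The pipeline takes a wide areas × indicators table plus an indicator
registry (thematic domain and direction per indicator) and runs the full
composite-index construction sequence:

1. **Imputation** — three deterministic fill rules: broadcast of upper-tier
   values to constituent areas, prior-year substitution, and peer-group
   means; every fill is logged.
2. **Suitability** — Kaiser–Meyer–Olkin sampling adequacy and Bartlett's
   test of sphericity on the indicator correlation matrix.
3. **Dimension reduction** — PCA of the correlation matrix, Horn's parallel
   analysis (adjusted eigenvalues > 1) to fix the number of retained
   components, and varimax rotation of the retained loadings.
4. **Weighting and aggregation** — indicators are assigned to the component
   with their largest absolute loading, weighted by normalised squared
   loadings, turned into sub-index scores from direction-aligned percentile
   ranks, scaled by component eigenvalues and summed into the composite.
5. **Sensitivity** — an unweighted variant grouped by the six thematic
   domains, compared by Spearman rank correlation.
6. **Evaluation** — regional ANOVA, north/south, coastal/inland and
   urban/rural t-tests; validation against a reference deprivation rank
   with OLS outlier detection; SD-from-mean bins for mapping (attachable to
   GeoJSON).

A 44-indicator reference registry ships as package data, and a seeded
synthetic generator (`resindex.synthetic`) produces tables with a known
latent-factor structure, area metadata, nested lower-level geography, the
three missingness patterns and a negatively-correlated reference index, so
the whole pipeline is testable without external data.

## CLI

```sh
# seeded synthetic dataset (values, metadata, registry, truth, reference, LSOAs)
resindex simulate --seed 1 --areas 307 --indicators 44 --factors 5 --outdir sim/

# full construction pipeline on CSV inputs
resindex build-index --values sim/values.csv --meta sim/area_meta.csv \
    --reference sim/reference.csv --seed 1 --outdir out/

# geographic comparisons / reference validation of an existing score column
resindex compare-geo --scores out/index_weighted.csv --meta sim/area_meta.csv
resindex validate --scores out/index_weighted.csv --reference sim/reference.csv

# simulate + build in one step
resindex full-run --seed 1 --outdir run/
```

`build-index` writes eigenvalue/loading tables, indicator weights,
percentile ranks, weighted and unweighted index tables, contribution
shares, geographic comparisons, validation reports, map bins, the
imputation log and a JSON run manifest (config echo, seed, versions,
per-stage log) sufficient to reproduce the run.

Pipeline knobs (percentile convention, Kaiser normalisation, parallel-
analysis reps/quantile, weight mode/basis, sub-index weight source, Welch
t-test, exclusions) live in `PipelineConfig`, loadable from YAML with CLI
overrides.

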