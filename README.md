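# corridorscope

Seasonal migration-corridor modelling on raster landscapes: two habitat
suitability models (a from-scratch presence-only maximum-entropy model and an
expert-based Analytic Hierarchy Process model) crossed with two connectivity
models (least-cost corridors and circuit-theory current maps), plus percentile
corridor slicing, GPS capture-rate evaluation, and a tiered priority-area
overlay. Everything runs end-to-end on synthetic prairie landscapes and
synthetic migratory telemetry with known ground truth, so every stage is
testable without field data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: oracle equivalence
(shortest paths vs networkx, circuit voltages vs dense solves), analytic
limits (series/parallel resistance, geometric cost distances, consistent-matrix
weight recovery), conservation laws (Kirchhoff, Gibbs normalization, L1
constraint satisfaction), synthetic-data recovery (NDVI contribution ranking,
held-out AUC, migration-window overlap, exact 17/42 + 18/42 migrant splits),
corridor structure (threshold nesting, capture monotonicity, tier nesting,
the circuit-vs-least-cost connection contrast), and exact statistic fidelity
fixtures.

## CLI

```sh
corridorscope run --config config.yaml --out runs/demo --seed 1
corridorscope validate --config config.yaml
corridorscope prep --config config.yaml --out runs/demo   # stages: simulate,
# prep, fit-hsm, connect, evaluate, tiers (each runs the pipeline up to itself)
```

Minimal config (all other keys have defaults; unknown keys are rejected):

```yaml
seed: 1
landscape: {nrows: 120, ncols: 120, cellsize: 750.0}
telemetry: {n_individuals: 42, n_spring_migrants: 17, n_fall_migrants: 18}
hsm: {beta: 0.5, background_size: 10000, test_frac: 0.25}
connectivity: {neighborhood: 8, circuit_aggregation: 3, basis: area_percentile}
thresholds: [1, 5, 10, 15, 20]
```

A run writes, under `--out`: the covariate rasters and fence lines
(`simulate/`), detected windows and pooled seasonal points (`prep/`), fitted
models, suitability and resistance surfaces (`hsm/`), habitat patches,
corridor and current surfaces (`connect/`), the 40-record factorial
evaluation table (`evaluate/`), the tier overlay (`tiers/`), and a
`manifest.json` of content hashes (identical config + seed gives identical
hashes).

## Layout

| module | contents |
| --- | --- |
| `corridorscope.raster` | grid model, ESRI ASCII + GeoTIFF I/O, distance transforms, resampling, reclassification |
| `corridorscope.landscape` | synthetic covariate stacks, parcels/roads, fence modelling + accuracy, truth model, survey generator |
| `corridorscope.telemetry` | suitability-biased migratory movement simulation |
| `corridorscope.migration` | daily displacements, window detection, migrant classification, seasonal pooling |
| `corridorscope.maxent` | presence-only maxent (greedy L1 coordinate ascent), AUC, contributions, jackknife, resistance transform |
| `corridorscope.ahp` | pairwise matrices, eigenvector weights, consistency ratio, survey aggregation, weighted suitability |
| `corridorscope.lcm` | cost-distance, corridor surfaces, least-cost paths, percentile slicing |
| `corridorscope.circuit` | conductance networks, focal-region contraction, current maps, effective resistance |
| `corridorscope.evaluate` | patch identification, capture statistics, factorial evaluation, tier overlay |
| `corridorscope.pipeline` / `corridorscope.cli` | configuration, staged orchestration, manifests |
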