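# bvocanom

Driver attribution of long-term biogenic VOC (BVOC) emission anomalies.

The package decomposes the fractional change of emissions relative to a
reference year (default 1978) into per-driver contributions — vegetation
biomass via NDVI regression, an exponential temperature activity, a
power-law CO2 inhibition of isoprene, a linear soil-moisture term, and
discrete wildfire burnt-biomass events — and recombines them with a
biomass-environment interaction term and per-driver error margins. On top of
the scalar pipeline it provides seasonal-amplitude analysis, per-pixel
anomaly mapping with atmospheric-mixing smoothing, scenario backcast and
projection from temperature/CO2 trajectories (including trend-reversal
detection), and synthetic-data generators with known ground truth so every
stage is testable offline.

## Layout

| Module | What it does |
| --- | --- |
| `bvocanom.drivers` | Per-driver response functions and the wildfire emission calculus |
| `bvocanom.attribution` | Contribution combination, interaction term, error propagation, anomaly series, moving averages, piecewise slopes |
| `bvocanom.seasonality` | Intra-year amplitude change and seasonal emission amplification |
| `bvocanom.spatial` | Per-pixel anomaly fields and kernel-mean mixing smoothing |
| `bvocanom.scenarios` | Trajectory-driven backcast/projection and reversal-year detection |
| `bvocanom.synthetic` | Seeded generators for driver series, vegetation grids, NDVI stacks, fire events |
| `bvocanom.config` / `bvocanom.io` / `bvocanom.cli` | YAML configuration, format round-trips, command-line entry points |

All contributions are dimensionless fractions internally; percent appears
only at I/O. Coefficient defaults (temperature coefficient 0.1 /degC, CO2
sensitivity 0.33, isoprene share 0.5, dry-mass scaling 0.5, background rate
0.26 kg/ha/day, margins 3/3/10/20%) live in `ResponseParams`/`ErrorBudget`
and can be overridden from a YAML config.

## CLI

```bash
bvocanom simulate  --seed 1 --out-dir out            # synthetic drivers, grid, fire events
bvocanom attribute --out-dir out                     # net-anomaly report from the packaged worked examples
bvocanom seasonal  --out-dir out                     # seasonal amplification report
bvocanom map       --seed 1 --out-dir out            # per-pixel anomaly + 15 km smoothing
bvocanom project   --trajectory strong_warming --out-dir out
```

Every run writes a `manifest.json` (config hash, seed, version); identical
config and seed give byte-identical CSV/JSON outputs. `--config` points at a
YAML file; `--seed`, `--reference-year`, `--radius-km` override it.

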