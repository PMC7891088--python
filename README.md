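# paleorange

Climate-stratified ecological niche modelling on synthetic data: from
monthly climate grids to bioclimatic variables, environmental strata and
zones, a MaxEnt-style Poisson point-process suitability model,
categorical per-stratum favourability maps under multiple climate
scenarios, and latitude-weighted area-change reports.

Everything runs on seeded synthetic inputs — a parametric climate
generator with a movable "pluvial belt", pseudo-GCM ensembles, land
masks with a sea-level knob, and occurrences sampled from a known
log-linear intensity — so the whole pipeline is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `synthetic_data` | seeded generators: climates, pseudo-GCM ensembles, land masks, occurrences, range masks, land cover |
| `bioclim` | growing degree-days (0 °C base), temperature seasonality (SD×100), aridity index (P/PET, Hargreaves), PET seasonality (CV×100) |
| `stratification` | standardise → PCA → k-means strata (default 125) → agglomerated, warmth-ordered zones (default 18); nearest-centroid classification of any climate slice |
| `niche_model` | L1-penalized Poisson point-process fit on presence + background cells, raw (relative occurrence rate) prediction, k-fold and two-scale checkerboard spatial CV, modified lowest-presence threshold (10 % omission allowance) |
| `suitability_mapping` | per-stratum favourability categories (unsuitable → highly favoured), cellwise modal ensemble combination with joint/uncertain classes, joint-class collapse |
| `area_report` | spherical cell areas, per-category area/percent accounting, time-slice change tables, range and land-cover cross-tabulations |
| `io_cli` | ASCII-grid raster I/O, occurrence CSV I/O, YAML run config, the end-to-end pipeline and its stages |

## CLI

```bash
paleorange write-config --out cfg.yaml       # dump the default config
paleorange run --config cfg.yaml --out out/  # full pipeline
# or stage by stage (composes to identical artefacts):
paleorange simulate --config cfg.yaml --out out/
paleorange bioclim  --config cfg.yaml --out out/
paleorange stratify --config cfg.yaml --out out/
paleorange fit      --config cfg.yaml --out out/
paleorange project  --config cfg.yaml --out out/
paleorange combine  --config cfg.yaml --out out/
paleorange report   --config cfg.yaml --out out/
```

Outputs are plain-text ESRI ASCII grids with JSON sidecars, CSV tables
and a `manifest.json` of artefact hashes; runs are deterministic for a
given config and seed. Exit codes: 0 success, 1 user error, 2 internal
error.

Default run constants mirror the reference analysis: 125 strata / 18
zones, regularization multiplier 2, 100,000-background-point ceiling,
10 % omission allowance, and 9-member mid-Holocene / 3-member LGM
ensembles. The full default run completes in about a minute on one CPU.

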