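# ravenrange

Movement and anthropogenic-food-source (AFS) analysis for GPS-tracked
corvids, built around the workflow used to study non-breeding common ravens
(*Corvus corax*) in the Alps: where do individuals range, which human food
sources (game parks, refuse sites, alpine huts) do they exploit, and how do
age, origin, sex and season shape both.

The package is aimed at movement ecologists who have Movebank-style GPS
tracks plus a table of individual attributes, and want the full chain from
raw fixes to model-averaged effect sizes — or who want to study that chain
itself on synthetic data with known ground truth.

## What it computes

For each *individual-season-year* segment (one bird's daytime fixes within
one astronomical season):

- **Occurrence distribution** — the 95% utilisation-distribution (UD)
  contour area from a dynamic Brownian bridge movement model (dBBMM). The
  position between fixes `i` and `i+1` at interpolation fraction
  `a ∈ [0,1]` is bivariate normal with mean `(1−a)·z_i + a·z_{i+1}` and
  variance `T·a(1−a)·σ²_m + (1−a)²δ² + a²δ²`, where `T` is the time lag,
  `δ` the GPS location error and `σ²_m` (m²/s) the Brownian motion
  variance, estimated locally in sliding windows (default window 31,
  margin 13) by maximising the leave-one-out likelihood of interior fixes,
  with a single BIC-screened behavioural breakpoint per window.
- **Maximum daily displacement** — the greatest great-circle distance
  between a day's first fix and any later fix that day, averaged per
  segment.
- **AFS detection and buffer calibration** — candidate sites are density
  clusters of 15-min-subsampled fixes (≥ 10 fixes within 200 m); each
  site's buffer is the radius where the revisitation count (maximal runs
  of consecutive in-circle fixes) stops increasing, capped at 150 m.
- **AFS-use metrics** — number of distinct site buffers a segment
  intersects, and the proportion of its fixes inside any buffer.
- **Inference** — four GLMMs (log-normal occurrence and displacement,
  Poisson AFS count, binomial presence probability with an
  observation-level random effect), each with a random intercept per
  individual, fitted by maximum likelihood with adaptive Gauss–Hermite
  quadrature; all 2^p fixed-term subsets ranked by AICc; candidate models
  (ΔAICc ≤ 6) averaged with Akaike weights, reported as estimates,
  unconditional SEs, 95% CIs and relative variable importance (RVI), plus
  back-transformed effect sizes (`100·(e^β − 1)` percent change on log
  scales, `1/(1+e^{−η})` probabilities on the logit scale).

A first-class synthetic-population generator (`ravenrange.synth`) emulates
the study design — cohorts of wild-caught/captive-released,
juvenile/adult birds released at a central game park, season-dependent
sampling rates, daytime-biased fixes plus a nightly roost fix, censoring —
with configurable log-scale effect sizes, so every stage is testable
against known ground truth.

## Worked example

```python
from ravenrange import synth, pipeline

cfg = synth.SyntheticConfig.scaled(n_individuals=12, n_sites=6, n_days=40, seed=7)
synth.simulate_population(cfg, "example")

pcfg = pipeline.PipelineConfig(
    tracks="example/tracks.csv", attributes="example/individuals.csv",
    out_dir="example/out", seed=7,
    model={"terms": ["age_class", "origin", "fixes_per_day"]},
)
result = pipeline.run_pipeline(pcfg)
print("segments:", result.counts["segments"], " calibrated sites:", result.counts["sites"])
print(pipeline.render_tables({"occurrence": result.batteries["occurrence"]}))
```

prints

```
segments: 12  calibrated sites: 27
== occurrence (n = 12) ==
term          level               estimate   unc_se   ci_low  ci_high    rvi      bt_est  flag
Intercept     Intercept             5.5936   0.5251   4.5645   6.6227      -  26770.5080
origin        wild-caught           0.4920   0.0897   0.3162   0.6679   1.00     63.5662  *
age_class     juvenile             -0.1616   0.0425  -0.2449  -0.0783   0.08    -14.9192
fixes_per_day fixes_per_day        -0.0408   0.0016  -0.0439  -0.0377   0.12     -3.9950
```

Reading the table: the occurrence response is modelled on the natural-log
scale, so the wild-caught coefficient 0.49 back-transforms to a +64%
larger occurrence area than captive-released birds, with RVI 1.00 (the
term appears in every candidate model — flagged `*` when RVI > 0.8). The
27 calibrated sites include the 6 true feeding sites plus smaller
well-revisited areas, mirroring the screening step that field studies
resolve with satellite imagery. A generated dataset this small supports
only coarse inference; the age-class RVI of 0.08 shows the battery
correctly declining to spend weight on a term this n cannot resolve.

The same pipeline runs from the shell:

```bash
ravenrange simulate --out example --seed 7
ravenrange all --config pipeline.yaml --seed 7 --out example/out
```

Outputs per run: `segments.csv`, `sites.csv`, `buffers.geojson`,
`revisitation_curves.csv`, `model_data.csv`, per-response model-set and
averaged-estimate CSVs, a rendered `report.txt`, and a `manifest.json`
(config hash, seed, versions, per-stage record counts). UD rasters can be
written as ESRI ASCII grids and contours as GeoJSON via
`UDRaster.to_ascii_grid` and `movement_metrics.contour_geojson`.

## Layout

| module | role |
|---|---|
| `ravenrange.synth` | synthetic populations with ground truth |
| `ravenrange.trackprep` | Movebank CSV reading, daytime filter, seasons, ages, segmentation |
| `ravenrange.movement_metrics` | dBBMM motion variance, UD rasters, contour areas, displacement |
| `ravenrange.afs` | site detection, revisitation curves, buffers, use metrics |
| `ravenrange.mminfer` | GLMMs, AICc subsets, model averaging, back-transforms |
| `ravenrange.pipeline` / `ravenrange.cli` | orchestration, reporting, `ravenrange` command |
| `ravenrange.solar` / `ravenrange.geo` | NOAA-style sunrise/sunset, local projection, distances |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
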