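# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `ravenrange`. It is the package's own account of its
science; every empirical statement here is recomputed by the test suite or
by `scripts/acceptance.py`.

## Analysis unit and preprocessing

The analysis unit throughout is the **individual-season-year segment**:
one bird's daytime fixes within one astronomical season of one calendar
year. Seasons split at March 21 / June 21 / September 23 / December 21,
taken at local civil midnight; "local" is a configurable fixed UTC offset
(default +1 h, the study region's standard time), avoiding any dependency
on a timezone database. A December–March winter therefore carries two
year labels, one per calendar year — the year covariate's levels are
calendar years, and the final year of a multi-year study exists only as
January–March winter data.

Daytime filtering keeps fixes between sunrise and sunset, both computed
per fix from its own coordinates and date with the NOAA general
solar-position equations (Julian-century polynomials, equation of time,
hour angle at zenith 90.833°). Accuracy is better than 2 minutes at mid
latitudes; latitudes at or beyond 66.5° are rejected rather than
mishandled during polar day/night. "Start of sunset" is interpreted as
the sunset instant itself (solar zenith 90.833°); the threshold is a
parameter for anyone preferring a civil-dusk reading.

Age class: juveniles hatch in spring, so a bird tagged as a juvenile
becomes adult at the first March 21 strictly after its tagging date; birds
tagged as adults stay adults. Because this transition coincides with a
season boundary, age class is constant within every segment.

Cluster detection input is thinned to a ≥ 15-min inter-fix interval by a
greedy forward pass per individual (first fix always kept); this is the
conventional guard against dense summer sampling dominating density
estimates. Thinning is per individual: pooling before thinning would let
one bird's fixes mask another's.

## Spatial reference

All planar work happens in a local azimuthal-equidistant projection on the
IUGG mean sphere, centred on the data (or simulation) centroid.
At the ~50 km scale of an alpine study area the pairwise-distance
distortion is below 2×10⁻⁴ (checked in the test suite), well under GPS
error; distances from the projection centre are exact by construction.
Displacement metrics use haversine great-circle distances directly, so
they are independent of the projection. A UTM zone would serve equally;
the AEQD form was chosen because forward and inverse transforms are
closed-form, which keeps simulated ground-truth geometry exact without a
CRS library.

## Dynamic Brownian bridge movement model

The bridge between consecutive fixes `i, i+1` (time lag `T ≤ 5 h`; longer
gaps split the track into independent bursts) places the animal at
interpolation fraction `a` as an isotropic bivariate normal with mean
`(1−a)z_i + a z_{i+1}` and variance

    s(a) = T·a(1−a)·σ²_m + (1−a)²·δ² + a²·δ²

with `δ = 20 m` location error and `σ²_m` the Brownian motion variance in
m²/s.

**Motion variance estimation.** Windows of 31 fixes slide one fix at a
time. Within a window, each interior fix contributes a leave-one-out
term: its likelihood under the bridge spanning its two neighbours (terms
whose flanking interval exceeds 5 h are skipped). `σ²_m` maximises the
summed log-likelihood via golden-section search on `log σ²_m` over
[1e−6, 1e4] m²/s (bracket shrunk below 1e−8; the 1-D profile is
unimodal). A single breakpoint leaving ≥ 13 fixes (the margin) on each
side is accepted iff it lowers BIC — `2·nll + k·ln(m)` with `m` the
number of leave-one-out terms — against the homogeneous fit. A fix's
`σ²_m` is the mean over all windows covering it; margin fixes inherit the
nearest interior value; segments shorter than one window fall back to a
single flagged global estimate, and segments under 3 fixes are skipped.

Two properties of this likelihood are worth knowing. First, as in the
standard formulation, the left-out fix's **own** location error does not
appear in `s(a)`; when GPS noise is large relative to motion
(`δ² ≳ T·σ²_m/4`) the estimate absorbs roughly `1.5δ²/(T·a(1−a))` of
extra variance. Raven flight data are strongly motion-dominated, where
this term is negligible; the simulation-recovery test uses δ = 5 m at
σ²_m = 2 m²/s for the same reason. Second, a two-state (dwell/transit)
animal is not Brownian, and transit-adjacent triples produce large
`σ²_m`; this is the intended behaviour — the bridge widens where the
animal commutes.

**UD rasterisation.** Bridge Gaussians are integrated over time onto a
100 m raster. Each sample deposits its exact per-cell mass (products of
axis-wise normal CDF differences) rather than a centre-point density, so
cell masses match fine-grid quadrature to well under 2% wherever mass
exceeds 1e−4. Sampling along the bridge is adaptive: Gaussian kernels
spaced at most one SD apart reproduce the continuous integral essentially
exactly (Poisson summation), so steps widen mid-bridge where the kernel
is broad and tighten to the configured 1-min timestep near the fixes
where the variance changes fastest. Footprints span 4.5 SD; the raster is
padded so no footprint is clipped; values below 1e−12 of the maximum are
zeroed before normalisation to unit mass.

**Contour area.** Cells are ranked by probability; the smallest prefix
reaching the contour level (default 0.95) defines the region, and the
area is the cell count times 0.01 km². This cell-prefix rule — not an
interpolated isopleth — is the documented convention here; on a
rasterised isotropic Gaussian (σ = 500 m) it reproduces the analytic 95%
disc area `π·χ²₂,₀.₉₅·σ²` within 5%, and doubling the cell size moves it
by under 10%.

## AFS detection, buffers, use metrics

Candidate sites are DBSCAN clusters (eps = 200 m, min 10 points) of the
thinned fixes, pooled over individuals; cluster centres are member-fix
centroids, and centroids within 200 m merge. The density reading of "at
least 10 fixes within 200 m" is one of two possible readings of the rule;
it is the one a point-pattern tool implements directly. Detection
over-fires by design on any well-revisited area (roosts, social spots) —
the field workflow resolves these with satellite imagery and
ground-truthing, which is out of scope; resource types are input labels.

A **revisitation curve** counts, per radius (default grid 20–150 m by
10 m), the maximal runs of temporally consecutive in-circle fixes of one
individual, pooled over individuals; a run interrupted by a data gap
longer than 5 h splits in two, consistent with the dBBMM burst rule.
Coverage (fixes inside) is monotone in radius; revisits need not be —
separate visits merge as circles grow. The **buffer** is the smallest
radius that no later radius improves by ≥ 5% (relative), else 150 m; the
explicit plateau rule replaces the visual "best estimate" of revisitation
plots so the choice is deterministic and testable. All-zero curves flag
the site unused (no buffer).

Per segment: `n_afs_visited` counts distinct buffers containing ≥ 1 fix
(a fix in two overlapping buffers counts toward both); the presence
proportion is fixes-in-union / total fixes, computed only for segments
with ≥ 1 visit — zero-visit segments are excluded from the presence
analysis rather than scored zero, since a bird released at a feeding site
that records no visit reflects sampling, not behaviour.

## GLMMs and multi-model inference

Four responses, matched to families: occurrence area and mean maximum
daily displacement as Gaussian mixed models on the natural-log response
("log-normal, identity link" — so coefficients back-transform to percent
changes); AFS count as Poisson/log; presence as binomial/logit on
(fixes inside, fixes outside) counts with an observation-level random
effect (OLRE) absorbing extra-binomial dispersion. Every model carries a
Gaussian random intercept per individual. The global fixed terms are age
class, origin, season, year, sex and the sampling-rate covariate
fixes-per-day; the binomial model omits fixes-per-day because its
response already conditions on sampling effort. Factors with fewer than
two observed levels drop out of a run's global model automatically.

Fitting is maximum likelihood. The Gaussian models go through
statsmodels' MixedLM (ML, with optimizer fallbacks). The Poisson and
binomial models are fitted in-package by adaptive Gauss–Hermite
quadrature: per-individual integrals are centred at the conditional mode
(Newton, analytic first/second derivatives) and scaled by the curvature,
with 15 (Poisson) or 11 (binomial) nodes; the OLRE integral nests inside
the individual integral and is itself adaptively centred per observation
— a plain ω-scaled grid is badly undersampled when trial counts reach
the hundreds. Standard errors come from the numerical observed
information at the optimum; when a variance component sits on its
boundary (τ → 0) the fixed-effect block is inverted alone. BFGS results
that stall on "precision loss" with a gradient below 2e−3 are accepted —
the boundary flattens the likelihood in the variance direction. Fits are
cross-checked in the test suite against lme4 (nAGQ = 15) and glmmTMB.
Marginal log-likelihoods include all constants (verified against direct
numerical integration), so AICc values are absolute.

All `2^p` subsets of the global fixed terms are fitted (factors enter and
leave whole); non-converged or AICc-undefined (n ≤ k+1) fits drop with a
logged count. Models are ranked by

    AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1)

and the candidate set is ΔAICc ≤ 6. Averaging is *conditional* (natural):
a coefficient averages over candidate models containing its term with
weights renormalised within that subset; full averaging with zero
substitution is available via `mode="full"` — published analyses rarely
state which was used, and RVI values do not disambiguate. The
unconditional SE uses the revised weighted-mean-of-roots form
`Σ w'ᵢ √(varᵢ + (βᵢ − β̄)²)` (the original variance-sum form is the
`se_formula="original"` option). RVI is the summed candidate weight of
models containing the term, not renormalised. CIs are β̄ ± 1.96·SE.
Back-transforms: `100(e^β − 1)` percent change for log-scale families;
logistic probabilities for the logit family, with non-intercept rows
added onto the intercept (the level's predicted probability at reference
settings). VIF diagnostics use the generalised determinant form for
multi-level factors.

## Synthetic data generator

The generator emulates a tracking study's design, not raven
biomechanics: birds alternate stationary dwell bouts at point-like AFSs
(mean 2 h) with straight transits (10 m/s) and short drifting exploratory
bouts (mean 10 min at 3 m/s — drifting so foraging search does not
masquerade as a fix cluster), all within a daily exploration disk around
the release game park that every bird knows. Defaults mirror the study
scale: 81 individuals (56/81 wild-caught, 49/81 female, 51/81 juvenile at
tagging), 45 sites (3 game parks / 18 refuse sites / 24 huts,
winter-peaking huts), a July 2017–March 2020 span, ~5-min summer and
~1.5-h winter mean fix intervals (the coarse end of the real summer
range, which reached 1 s), one roost fix 6 h after sunset per night, and
a per-day censoring hazard of 0.0011 (≈ 36 track terminations among 81
birds over the span).

Cohort and season effects enter as log-scale multipliers on four
channels: exploration-disk radius (range; area scales as e^β so the
radius takes β/2), far-versus-near destination propensity
(displacement), known-site repertoire size (visits), and the probability
that a chosen destination is an AFS (presence). Default magnitudes echo
the published tables (juvenile range −0.84, wild-caught +2.20, …).
Between-individual heterogeneity is injected as iid normal offsets per
channel (SD 0.3/0.2/0.2/0.4) — the signal the individual random
intercept absorbs downstream. Sites are placed with > 300 m pairwise
separation (twice the maximum buffer) so detection is unambiguous. All
randomness derives from one seed through `SeedSequence.spawn`; a fixed
seed reproduces files byte-for-byte.

What the generator does **not** emulate — and hence what green tests do
not establish about field data: terrain and thermals, flocking and social
attraction, battery-driven sampling irregularity beyond the seasonal
means, transmitter position error structure beyond iid Gaussian noise,
true behavioural autocorrelation across days, and the satellite-imagery
screening that separates feeding sites from roosts. Detection counts on
synthetic populations therefore include well-revisited non-AFS areas, as
the raw cluster step does on real data before screening.

## Problem sizes

Tests and the acceptance script run scaled designs chosen as the smallest
that leave the tested signal clearly resolvable: e.g. 20 birds × 10 sites
× 24 days (hourly sampling) for end-to-end cohort-sign recovery over 20
replicates, 80 individuals × 5 observations × 100 replicates for Poisson
GLMM calibration, 200-fix tracks × 10 seeds for motion-variance
recovery. The full-scale default configuration (81 birds, 2.75 years)
generates on the order of 10⁶ fixes and is intended for offline use.

## Known limitations

- The bridge likelihood's neglect of the left-out fix's own GPS error
  (see above) biases σ²_m upward on noise-dominated tracks.
- The cell-prefix contour slightly underestimates smooth-isopleth areas
  at coarse cells; both conventions exist in the field.
- Conditional averaging shrinks nothing toward zero; terms with low RVI
  still display full-magnitude averaged coefficients. Read estimates
  jointly with RVI.
- DBSCAN's density reading of the cluster rule and the per-individual
  thinning are one interpretation of an under-specified published
  procedure; both are parameters.
- The binomial OLRE model treats fixes as exchangeable within a segment;
  temporal autocorrelation within days is not modelled.
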