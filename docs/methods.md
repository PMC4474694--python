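# Methods

This note records the models implemented in `seaniche`, the assumptions
behind them, the choices made where the design was genuinely open, and what
the synthetic tests do and do not demonstrate.

## Spatial containers

All fields live on one rectangular grid of square cells (default 1 km) with
a boolean marine mask; row 0 is the northernmost row and coordinates are
planar metres. Derived layers keep the input mask, except slope, which
drops cells with no valid neighbour. Rasters are exchanged as ESRI ASCII
grids written with 17 significant digits, so a write/read round trip is
bit-exact for float64 (the ingest-mode pipeline reads CSVs with
`float_precision="round_trip"` for the same reason).

## Environmental layers

**Depth.** Ordinary kriging of scattered soundings: the empirical
semivariogram is binned to half the maximum pair separation and an
exponential model γ(h) = c₀ + c₁(1 − e^{−3h/a}) is fitted by least squares
weighted by √(pair count); the kriging system uses γ(0) = 0 on the diagonal
and for coincident target/sounding pairs, so the interpolator is exact at
sounding cells. Soundings beyond 600 points are evenly thinned before the
solve. A constant sounding set short-circuits to a constant raster.
Inverse-distance weighting (power 2, 12 nearest) is available as the
configurable fallback. Extrapolation outside the sounding hull is allowed
(and is the least reliable part of the surface).

**Slope.** Per cell, the maximum over the up-to-eight valid neighbours of
atan(|z_n − z|/d) in degrees, with d = cell size for rook neighbours and
cell size·√2 for diagonals. Neighbours under the land mask are ignored
rather than treated as 0 m depth, which would fabricate coastal cliffs.

**Distance to shore.** Euclidean distance from each marine cell centre to
the nearest land cell centre (`scipy.ndimage.distance_transform_edt`). The
centre-to-centre convention is used because the synthetic coastline is a
cell boundary, not a vector polyline; a marine cell whose rook neighbour is
land is one cell size from shore.

**Seasonal SST statistics.** Months October–March form the warm season,
April–September the cold season. Per-cell mean and sample SD (n − 1
denominator — the dates are a temporal sample) over the dates assigned to
each season; a season with fewer than two dates is rejected because its SD
is undefined.

**Correlation screen.** Pearson on all jointly valid cells by default, with
Spearman as a flag (the two conventions disagree in parts of the
literature, so both are exposed). Pairs with |r| above the threshold
(default 0.7) are flagged; the screen is advisory — the pipeline logs a
warning and proceeds, leaving the drop decision to the analyst. Constant
layers yield NaN correlations with a warning.

## Maximum-entropy habitat model

The presence/background Gibbs formulation: over the training domain D
(background cells ∪ deduplicated presence cells), q(x) = e^{η(x)}/Z with
η = Σ_f λ_f f(x). The weights minimise

    J(λ) = −(1/m) Σ_presences η(x_i) + ln Z + Σ_f β_f |λ_f|,

which is solved exactly by splitting λ into positive and negative parts and
running L-BFGS-B with analytic gradients under non-negativity bounds; the
penalised objective is monotone non-increasing over accepted iterates (a
tested invariant). Non-convergence at `max_iter` (default 1000) returns the
model with a warning flag; the L1 penalty prevents infinite weights under
perfect separation.

*Features.* Covariates are min-max normalised over the training points, so
every feature is bounded to [0, 1] there. Auto-features enable classes by
presence count: linear always, quadratic ≥ 10, hinge ≥ 15, product and
threshold ≥ 80 (all overridable). Hinge and threshold knots sit on a uniform
lattice in normalised space, 8 knots per covariate by default; univariate
response-curve models use 16, since a single-variable model can afford the
finer lattice and it sets the resolution of the curve's optimum.
Regularisation scales are per-class constants interpolated against the
presence count (linear/quadratic/product 1.0→0.05 between 0 and 100
presences, hinge 0.5, threshold 2.0→1.0) times the feature's SD over the
presences (floored at 0.05) divided by √m, all times a user multiplier.

*Logistic output.* s = e^H q/(1 + e^H q) with H the entropy of the fitted
q, so q = e^{−H} ("typical" conditions) maps to 0.5. Prediction clamps
covariates to the training range (counted and logged) to avoid hinge
extrapolation artifacts.

*Evaluation.* AUC is the rank-based probability that a presence outscores a
background point, ties counted ½ (equals the trapezoidal ROC area; tested
against all-pairs counting). Cross-validation partitions presence cells
into k folds (default 25), fits on k − 1 and scores the held-out fold
against the full background; the per-cell mean and SD surfaces are taken
across replicate models. Permutation importance shuffles one covariate's
raw values across all training points, recomputes features and scores, and
reports the mean training-AUC drop over `n_permutations` shuffles, floored
at 0 and normalised to 100; if every drop is zero, importance is reported
uniform with a warning. The background is drawn uniformly without
replacement from all marine cells, independent of the presences.

*Response optimum.* Hinge-based univariate curves are piecewise linear and
plateau near their maximum, so the bare argmax rides the plateau edge;
`response_optimum` returns the centroid of the region ≥ 90 % of the curve
maximum, which is a markedly stabler location estimate.

## Directional overlap

Both surfaces are first intersected to their common valid-cell set, so one
r (and one degrees-of-freedom value) serves both directions. Each surface
is normalised by its own total N; SO_ik is computed in the log domain with
cells where p_ij = 0 excluded from both sums (0·ln 0 := 0), and equals the
naive product form to 10⁻¹⁰ on random distributions (tested). If p_k
vanishes somewhere p_i is positive, SO_ik = 0 exactly and the U test
reports an infinite statistic with a support-mismatch flag.

N_i in U_ik = −2 N_i ln SO_ik is, by default, species i's pre-normalisation
suitability sum over the shared cells — the published (SO, U) pairs this
workflow follows are numerically consistent with that reading — with a
config override to use the presence-locality count instead (the overlap
index's original usage in diet studies). The p-value is the exact
chi-square upper tail; with U far below r − 1 degrees of freedom it is
reported as 1 to machine precision rather than rounded.

## Group attributes

Group size is recorded only in ordered categories, so the two-sample KS
statistic is computed on bin-level CDFs without the continuous-data
correction; the p-value is the asymptotic Kolmogorov tail at
D·√(n₁n₂/(n₁+n₂)). Composition and activity use Pearson chi-square
contingency tests without Yates correction. Mixed-species-group records are
excluded from single-species distributions and summarised separately, and
composition/activity are tabulated only from the records where they were
collected (systematic surveys); empty fields are missing data, not a
category.

## Synthetic seascape: what it emulates, and what it does not

The generator produces a semi-enclosed gulf on a 100 × 100 grid of 1 km
cells: a half-elliptical basin opening eastward, a bowl bathymetry reaching
200 m at the centre grading into a ~60 m shelf at the mouth (the shelf also
keeps depth from being a mere proxy of distance-to-shore), a warm-season
thermal front with 1.6 °C NW–SE contrast (18.6 °C south-eastern base,
20.2 °C north-west), a near-uniform 13 °C cold season, and four upwelling
zones anchored at angular quantiles along the west and north coasts
(excluding the warm NW corner). Upwelling enters as antithetic per-date SST
anomalies normalised to unit sample SD, so `upwelling_sd` (default 1 °C) is
exactly the temporal SST-SD at a patch centre and the patches leave the SST
*mean* map untouched — SST-SD is a pure variability proxy, as in real
AVHRR-derived seasonal composites. Date-level offsets (SD 0.2 °C) and
per-cell noise (0.05 °C) complete the temporal structure.

Two stock species span the contrast the workflow is designed to resolve:

* **offshore_thermal** (narrow): 0.95·exp(−½((SST−19.4)/0.25)²) +
  0.55·ramp(SST-SD) + 0.005 — a thermal band along the front in the warm
  season, upwelling-variability habitat in the cold season; dominant
  covariates SST (warm) and SST-SD (cold).
* **coastal_slope** (broad): 0.08 + 0.85·min(slope/1°, 1)·e^{−dist/10 km} —
  steep seabed near shore with a non-zero floor everywhere; dominant
  covariates slope and distance-to-shore in both seasons. The floor makes
  the broad niche cover the narrow one, which is what gives the overlap
  index its directional asymmetry.

Sightings are drawn per season with probability proportional to truth ×
effort (effort: a coastal boost over a uniform floor, emulating coastal
transects plus offshore legs), with 400 sightings per species and season by
default (≥ 300 unique presence cells after deduplication), deliberate
duplicate records, survey-source labels, group attributes, and ~4 % of
records paired across species within 100 m as mixed-species groups.

*What passing tests show:* that the implementation recovers planted niches
— the top-importance covariate matches the generator in ≈ 97 % of models,
the overlap asymmetry SO(narrow→broad) > SO(broad→narrow) holds in ≥ 95 %
of season-level comparisons over 20 seeds, and the SST response optimum is
recovered with a median error of half a curve-grid step (individual seeds
can be off by up to ~2 steps, because heterogeneous effort biases the
univariate marginal — a limitation of presence-only response curves
themselves, not of the optimiser). *What they do not show:* performance
under real detection processes (distance-dependent detectability, sea-state
effects), spatially autocorrelated sampling effort beyond the smooth
coastal gradient, observation error in positions, or niches that drift
between years — none of which the generator emulates.

## Problem sizes and determinism

The recovery study runs 20 replicate seascapes at the full 100 × 100 grid
with 1000 background cells and a single fit per species × season (the
study measures recovery, not cross-validation spread); it completes in a
few minutes on one CPU. Unit and pipeline tests use 24–40-cell grids.
Every random draw descends from one master seed through
`numpy.random.SeedSequence` spawning (pipeline stage order: seascape,
occurrences, background, cross-validation, importance), so identical
configs reproduce byte-identical CSVs and bit-identical rasters, which the
run manifest verifies by checksum.

## Known limitations

* Kriging fits an isotropic exponential variogram only; anisotropy and
  alternative models are out of scope (the variogram parameters can be
  supplied explicitly).
* The logistic output compresses extreme suitabilities; overlap values from
  logistic surfaces are therefore closer to 1 than those from raw
  probability surfaces would be. Comparisons between directions and
  seasons are unaffected.
* With r ≈ 10⁴ cells the U test's effective sample size N_i is in the
  thousands, so statistically "significant" departures from complete
  overlap can be ecologically small; the exact p-values are reported and
  interpretation is left to the analyst.
* The correlation screen flags depth vs distance-to-shore (r ≈ 0.8) on the
  synthetic gulf; as in the workflow this package follows, flagged pairs
  are reported, not dropped.
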