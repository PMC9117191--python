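# Methods

## The question and the model

Two burrowing mammals leave countable surface signs: souslik nest
burrows (one animal per burrow in spring) and mole mounds (15–50 cm
spoil heaps). The analysis asks whether their co-occurrence over a
shared short-grass area is random, using a three-zone presence/absence
design: 10 m² circular plots centred on burrows (BURROW), random plots
inside the colony range excluding a 4 m band around burrows (COLONY),
and random plots outside the colony (CONTROL). Presence of mole signs
per plot is Bernoulli; the zone effect is estimated with a binomial
GLM (logit link, zone as a categorical factor, reference BURROW). The
model is saturated in one factor, so fitted per-zone probabilities
equal empirical proportions; its value is the inferential machinery —
Wald covariance for unadjusted (LSD-style) pairwise contrasts, and a
tie-corrected rank AUC as the discrimination summary. Complete
separation (an all-0 or all-1 zone) switches the affected contrasts to
Fisher's exact test, because Wald standard errors are infinite there.

Independence between plots is assumed; the survey design supports it
through the 8 m minimum spacing (non-overlapping plots) and the 4 m
exclusion band, not through an explicit spatial-correlation model.

## Occupied area

The occupied area of a point set is the 95% isopleth of a fixed-radius
uniform-disc kernel density: each point spreads unit mass over the
disc of radius r centred on it, discretised by cell-centre inclusion;
cells are accumulated in decreasing density order until 95% of the
mass is reached, and all cells tied at the threshold density are
included. Tie inclusion makes the estimator deterministic and gives
the intuitive answer for degenerate inputs (a single point yields the
whole disc, not 95% of a constant-density disc). A Gaussian kernel
(with r as sigma) is available behind a flag for sensitivity checks;
the disc is the default because the protocol specifies fixed search
radii (5 and 10 m for the mole range).

Regions are boolean cell masks: area is the cell count times the cell
area, and point-in-region is a cell lookup, so the zone partition
(colony + control + buffer band = landscape) is exact by construction.
Vector polygons, derived on demand by marching squares for GeoJSON
export, bevel cell corners and may differ from the mask area by up to
half a cell per boundary cell; the mask stays authoritative.

Default cell size is 1 m for occupied-area estimates (≤ r/2 for both
presets) and 2 m for zone construction in the large calibrated
scenario; a halving of the cell size moves the 95% area by well under
2% on 100-point test patterns.

## Synthetic landscapes

The generator emulates the study conditions rather than any particular
dataset:

* **Landscape** — a simple polygon; the default is a 2:1 rectangle of
  105 ha in local metric coordinates.
* **Burrows** — a minimum-spacing (10 m) pattern clustered around a few
  colony centres (3 centres, Gaussian spread 150 m), 228 burrows in the
  calibrated preset.
* **Mounds** — a Matérn-style cluster process: parents (tunnel
  systems) with mean cluster size 6 and dispersal radius 8 m, chosen as
  a realistic run of mounds along one tunnel system. Parents are drawn
  from a mixture of broad activity patches (9 Gaussians of spread 78 m)
  truncated to the landscape; offspring are re-drawn within their disc
  until inside the boundary, so the expected mound count is exactly
  `mound_base_intensity × area` before thinning. The patches encode the
  observation that mole activity concentrates in favourable parts of a
  site; without them the 95% isopleth would cover nearly the whole
  landscape instead of the observed one-quarter to one-half.
* **Avoidance** — independent thinning: a candidate mound within
  `avoidance_radius` (19 m in the preset) of any burrow is deleted with
  probability `avoidance_strength` (0.95). Thinning is exactly
  calibratable and sufficient to produce the zone gradient; a
  Gibbs/Strauss interaction model would be harder to calibrate and
  adds nothing the analysis needs.

The `airfield2019` preset constants were fixed once by a coarse grid
search against the zone model: over 15 seeds the per-zone presence
probabilities average 0.061 / 0.209 / 0.421 (BURROW / COLONY /
CONTROL) with the colony kernel radius at 25 m, and the mole KDE-95%
occupied fraction at the 10 m kernel stays within 0.32–0.48 of the
landscape.

One consequence of calibrating to plot frequencies: a CONTROL presence
probability of 0.44 in 10 m² plots forces a within-patch mound density
above 0.06/m², at which the 5 m kernel discs already tile the occupied
area — so the 95% isopleth, and with it the burrow-overlap fraction,
is nearly insensitive to the kernel radius on preset data (area ratio
r = 10 vs r = 5 of about 1.1). Radius sensitivity, including the
growth of burrow overlap with radius, is real and tested on sparse
mound maps where the kernel scale genuinely matters. Passing tests on
preset data therefore demonstrate the zone gradient, the occupied-area
bracket and the monotonicities, not the kernel-radius contrast of a
sparse field map.

## Synthetic orthoimagery and the baseline detector

Mounds render as bright ellipses (diameter uniform in 0.15–0.50 m,
minor/major aspect 0.8–1.0) with a dome profile `√(1−ρ²)` peaking
`mound_brightness_contrast` (0.25 image units) above the background's
99th percentile, over correlated noise (smoothed white noise,
correlation length 0.5 m, level 0.35 ± 0.06). Ground-truth boxes
tightly bound rendered pixels, half-open, origin top-left; the default
GSD is 2 cm and the renderer requires the smallest mound to span at
least 3 pixels. Tiles pad right/bottom edges with background-like
noise; a box clipped at a tile edge is kept in every tile retaining
≥ 50% of its area, and a box that no tile retains at 50% (a four-way
corner straddle) goes to the tile with the largest overlap so that
every truth box appears at least once. Shadows, soil radiometry,
phenology and the souslik's own elongated mounds are deliberately not
modelled — only the bright-blob signal a detector needs.

The baseline detector thresholds at a robust background estimate
(median + normal deviate of the background quantile × MAD-based sigma
+ contrast threshold) — robust so that dense mound fields cannot drag
a plain quantile estimate above the mounds themselves — labels
connected components, and keeps those whose equivalent diameter falls
in the 15–50 cm prior (±50% margin for rasterisation). Scores are
normalised mean brightness excess. It is a classical stand-in that
makes the evaluation chain executable end to end; its metrics
characterise the synthetic benchmark only, and published
deep-detector figures on real imagery are not reproduction targets.

Matching is greedy in descending score (ties by xmin, then ymin):
TP requires IoU strictly greater than the threshold (an overlap of
exactly 0.5 is a FP), duplicates of a matched truth are FPs, unmatched
truths FNs. Greedy matching can in principle undercount relative to
the optimal assignment in crossed configurations where some pairs
clear the threshold and others almost do; on random ≤ 6-box instances
the tests bound the discrepancy at one match, and when every
prediction-truth pair clears the threshold greedy is provably optimal
(both sides reach min(#preds, #truths)). AP is the all-point
interpolated area under the precision envelope at a single IoU
threshold, invariant to monotone score transformations.

## Numerical and convention choices

* Plot scoring uses mound centroid in the closed plot disc (a centroid
  at exactly the radius counts); multi-year zone means are unweighted
  means of yearly proportions by default, plot-weighted pooling behind
  a flag.
* Rejection sampling for plot centres (uniform conditional on
  acceptance), capped at 10,000 proposals per accepted point; cap
  exhaustion raises an error reporting how many points were placed.
* Per-zone aggregated GLM fitting (IRLS on 2–3 binomial rows) is
  numerically identical to the per-plot fit and keeps the Monte-Carlo
  calibration tests (2,000 null replicates, 1,000 power replicates)
  inside seconds.
* Master seed → per-stage seeds by fixed offsets (generation 10 + year
  index, plot sampling 100 + year index, imagery 200, tiling 210); the
  same configuration reruns byte-identically.
* Effort model: route 10/strip-width km/ha, 600/(speed × width) min/ha,
  person-days = ⌈area / 10 ha⌉; linear in area before day rounding.
* Reported tables round areas to 0.1 ha and fractions to the survey's
  reporting granularity (integer % for habitat shares, 0.1% for burrow
  overlap) while retaining raw values alongside.

## Problem sizes used in tests

Unit tests run on 100–200 m landscapes with tens of burrows and a few
hundred mounds; calibration properties use the full 105 ha preset (50
seeds for the occupied-area bracket, 20 three-year seeds for the zone
gradient); the avoidance-monotonicity grid runs 5 strengths × 100
seeds on a 6 ha landscape. The acceptance script executes one full
calibrated three-year scenario plus a 60 m imagery window centred on
the densest mound patch.

## Known limitations

* No observer-error or GPS-accuracy model; scoring is deterministic
  centroid-in-disc.
* No spatial-autocorrelation or mixed modelling beyond the design's
  spacing; no multiplicity adjustment beyond LSD semantics.
* Kernel-radius insensitivity on frequency-calibrated synthetic data,
  as discussed above.
* The landscape polygon is convex-rectangular by default; irregular
  real boundaries are supported but untested against field data, which
  are not publicly deposited.
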