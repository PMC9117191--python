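# burrowscape

Spatial-avoidance analysis between burrowing mammals, built around the
case of the spotted souslik (*Spermophilus suslicus*) and the European
mole (*Talpa europaea*) coexisting on a ~105 ha short-grass airfield.
The package is aimed at spatial ecologists and conservation monitoring
teams who want to (a) test whether two burrowing species co-occur at
random or avoid each other, (b) delineate occupied areas from mound or
burrow maps, (c) evaluate automated mound detectors on aerial imagery,
and (d) budget transect survey effort — with a synthetic-landscape
generator so the whole chain is testable without field data.

## What it computes

**Zones and sampling.** The study area splits into three survey zones:
BURROW (a 10 m² circular plot, radius √(10/π) ≈ 1.784 m, around every
inhabited nest burrow), COLONY (the burrow kernel-density 95% isopleth
minus a 4 m buffer band around burrows) and CONTROL (the rest).
Random plot centres keep a minimum spacing of 8 m within each zone.

**Occupied area.** For a point set {xᵢ} the density surface is a
fixed-radius uniform-disc kernel, f(x) = Σᵢ 1{‖x−xᵢ‖ ≤ r}/kᵢ on a
raster grid (each point contributes unit mass), and the occupied area
is the 95% isopleth: cells accumulated in order of decreasing density
until 95% of the mass is covered, ties included. Radius presets r = 5
and 10 m are used for the mole range.

**Avoidance statistics.** Presence/absence of mole signs on plots is
modelled by a binomial GLM, logit P(present) = β₀ + β_zone, fit by
IRLS (statsmodels). The model is saturated in the zone factor, so the
fitted per-zone probability equals the empirical proportion; AUC is
the tie-corrected rank (Mann–Whitney) statistic, and pairwise zone
contrasts are unadjusted (LSD-style) two-sided Wald z tests on the
log-odds scale, falling back to Fisher's exact test under complete
separation.

**Detection evaluation.** Greedy score-ordered box matching with
TP ⇔ IoU > 0.5 (a duplicate detection of a matched truth is a FP),
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), and
all-point interpolated average precision. A classical bright-blob
detector with a 15–50 cm size prior serves as the built-in baseline.

**Habitat and effort.** Remaining habitat = total − mole area; burrow
overlap fraction = share of burrows inside the mole isopleth. Transect
effort from walking speed v (default 3 km/h) and strip width w
(default 5 m): route 10/w km/ha, time 600/(vw) min/ha, one person-day
per 10 ha.

**Synthetic landscapes.** Burrows form an inhibited (≥ 10 m spacing)
clustered pattern; mounds are a Matérn-style cluster process (tunnel
clusters nested in broad activity patches) thinned near burrows: a
candidate mound within the avoidance radius of any burrow is deleted
with probability equal to the avoidance strength. The `airfield2019`
preset (228 burrows, ~105 ha) is calibrated so per-zone presence
probabilities land near 0.06 / 0.18 / 0.44. Orthoimagery renders
mounds as bright ellipses on correlated background noise with tight
truth boxes, tileable to labelled 256×256 patches.

## Worked example

```python
import burrowscape as bc
from burrowscape.pipeline_cli import ScenarioConfig, run_year

cfg = ScenarioConfig.from_preset("airfield2019", seed=1)
plots = []
for i, year in enumerate(cfg.years):
    burrows, mounds, zones, scored = run_year(cfg, year, i)
    plots += scored
print(bc.pooled_means(bc.frequency_table(plots)).round(3))
fit = bc.fit_zone_model([p for p in plots if p.year == 2019])
print({z.value: round(p, 3) for z, p in fit.fitted_probability.items()},
      "AUC", round(fit.auc, 3))
```

prints

```
zone
BURROW     0.056
COLONY     0.173
CONTROL    0.363
Name: proportion, dtype: float64
{'BURROW': 0.065, 'COLONY': 0.29, 'CONTROL': 0.35} AUC 0.714
```

i.e. mole signs appear on ~6% of plots at burrows, ~17% elsewhere in
the colony and ~36% outside it — the avoidance gradient the zone model
then confirms (BURROW–CONTROL contrast p < 10⁻⁸ for this seed).
The effort model from the shell:

```sh
$ burrowscape effort --area-ha 40
{ "minutes_per_ha": 40.0, "route_km_per_ha": 2.0, "total_minutes": 1600.0,
  "total_hours": 26.67, "total_route_km": 80.0, "person_days": 4, ... }
```

Skipping a 40 ha mole-occupied area therefore saves about 27 hours, an
80 km route and 4 person-days per survey round.

A full scenario — generation, zoning, scoring, zone models, imagery,
detection and habitat accounting, with a reproducibility manifest —
runs with `burrowscape run --preset airfield2019 --seed 1 --out out/`.

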