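# canopymort

Canopy structure and drought-induced tree mortality: a tested, reusable
analysis pipeline for forest ecologists working with lidar-style canopy
height models and individual-tree inventories.

During severe droughts, whether a tree lives or dies depends not only on its
own size but on the canopy around it. This package implements the full chain
needed to study that question on a forest scene (tree list + canopy height
model + terrain):

- **Neighborhood competition indices** — CCTH (percent of a circular
  neighborhood covered by canopy taller than the subject tree), CC66 (taller
  than 66 % of its height) and CVTH (coefficient of variation of neighbor
  heights), at configurable radii (15 / 30 / 50 / 100 m).
- **Crown shadow ratios** — points sampled on each tree's crown envelope
  (vertical cone for conifers, sphere for broadleaves) are ray-traced toward
  the sun at 23 half-hour steps across a mid-summer day; the daytime-mean
  shaded fraction quantifies how much neighbors shelter a crown from
  radiation load. A reduced two-leaf model converts added shadow into a
  relative transpiration (ET) decrease.
- **Dead-tree calling** — per-crown dead-pixel fractions from a land-cover
  classification, the strict "over 35 %" call rule with a 30–50 % threshold
  sweep, pre-drought exclusion, and cohort mortality rates in %/yr per
  forest stand or regular grid cell.
- **Crown segmentation** — marker-controlled watershed on the CHM with the
  <5 m removal rule, plus a matching harness that scores recall/precision/F
  against known stems.
- **Terrain covariates** — Horn slope/aspect, D8 flow accumulation,
  TWI = ln(a / tan β), and a clear-sky solar radiation surface.
- **Statistics** — tree-count-weighted binning; weighted linear and
  continuous piecewise (segmented) regression with exhaustive breakpoint
  search and BIC selection; beta regression for proportion outcomes; a
  random-intercept mixed model with height-class groups; bootstrap mediation
  (competition → shadow → mortality); random-forest importance and partial
  dependence for the combined structure + environment drivers.
- **Synthetic scenes** — a generator with clustered stems (Thomas process),
  elevation-dependent genus niches (*Abies* highest, then *Cedrus*, *Pinus*,
  *Quercus*), per-genus height distributions (oak capped at 24 m), crown
  allometry, and a known ground-truth mortality process (piecewise
  negative-positive-negative height effect, negative CCTH effect), so every
  stage is testable for parameter recovery without any data download.

Rasters are carried in a lightweight `Raster` container with ESRI ASCII grid
(`.asc`) text I/O; tree tables are pandas DataFrames (CSV), stands are
GeoJSON polygons.

## The statistics at the core

Per statistical unit *u* (stand or grid cell) and bin *b* along a structural
attribute, the mortality rate is

    r_ub = 100 · n_dead,ub / n_ub / years        [%/yr]

and all regressions weight each (u, b) observation by its tree count n_ub.
The piecewise height model is continuous with hinge terms,

    r(h) = β₀ + s₁·min(h, k₁) + s₂·clip(h−k₁, 0, k₂−k₁) + s₃·max(h−k₂, 0),

with breakpoints (k₁, k₂) chosen by exhaustive search over bin centers and
weighted BIC across 0/1/2-break models. The beta regression models the
proportion p = r·years/100 as Beta(μφ, (1−μ)φ) with logit(μ) linear in the
covariate, fit by weighted maximum likelihood. The mediation analysis
estimates a (exposure→mediator), b (mediator→outcome | exposure) and the
indirect effect a·b with a seeded percentile bootstrap.

## Worked example

`examples/07_driver_statistics.py` simulates binned mortality series with
known truth and fits them:

```
piecewise fit: 2 breaks at [13.0, 39.0], slopes [-0.362, 0.239, -0.199], R2=0.994
CCTH slope: WLS -0.0163 %/yr per % (p=1.5e-28); beta-regression slope -0.0157 on the logit scale
mediation: a=0.118, b=-0.185, indirect=-0.0219 [-0.0270, -0.0165], direct=0.0039
```

The piecewise fit recovers the negative-positive-negative height response
(true breaks 14 m and 39 m) — mortality falls with height for small trees,
rises for mid-sized trees, falls again for the tallest. Both regression
routes agree on the negative CCTH slope: trees with more taller neighbors
die less. The mediation CI excluding zero shows the competition effect
acting through crown shadow, with a direct effect near zero.

The other `examples/` scripts each demonstrate one capability (scene
generation, segmentation, terrain, competition, shadow + ET, mortality
rates, full pipeline); run them with `python examples/<name>.py`.

`pipeline.run_all(RunConfig(...), outdir)` executes the whole chain — one
global seed derives every stage seed, and a rerun with the same
configuration is byte-identical.

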