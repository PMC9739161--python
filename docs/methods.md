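# Methods

This note documents the models, the synthetic study system, the numerical
choices, and what the tests do and do not establish.

## Grid model and conventions

All layers live on planar metric grids: row 0 is north, a value refers to
the whole cell (area convention), the origin is the outer corner of the
top-left cell, and there is no reprojection — one coordinate frame
throughout. Continuous layers use a −9999 nodata sentinel; categorical
land-use layers use 0, so the sentinel can never collide with the class
codes 1–6 (arable, forest, grassland, water, built-up, bareland). Files
are single-band TIFFs with a JSON sidecar carrying cell size, origin,
nodata, units and the legend.

Resampling: continuous layers are aligned bilinearly between cell
centres (edge values extended past the outermost centres); categorical
layers by nearest neighbour. Majority aggregation assigns each fine cell
to the coarse cell containing its centre — exact block counting when the
cell-size ratio is an integer, and well defined otherwise, which the
30→40,50,…,300 m grain series requires. Ties take the smallest class
code; a coarse cell is nodata iff more than half its contributors are;
trailing partial rows/columns are truncated (the coarse grid spans
`floor(extent/grain)` cells per axis).

## The synthetic island

One integer seed determines every layer (each layer draws from its own
`SeedSequence` child). The default island is 300×300 cells at 30 m, a
disk of radius 0.48·(short side) — roughly 65 000 land cells — with sea
(nodata) outside. Design intent: reproduce the *statistical relationships*
a coastal-urbanising tropical island analysis assumes, at desk scale, so
that every downstream stage has a known right answer.

- **DEM**: radial cone peaking at 650 m (inside the 500–800 m interior
  band), zero at the coast, plus Gaussian-smoothed noise (amplitude 8 m,
  correlation length ~8 cells). With noise off, elevation is strictly
  non-increasing with distance from the centre.
- **Land use**: class areas hit the epoch-1 targets (63 % forest, 26 %
  arable, 4 % grassland, 3 % water, 2.5 % built-up, 1.5 % bareland) by
  quantile allocation on an elevation-plus-noise score: forest on the
  high interior, water on the lowest coastal cells, built-up by a
  coastal suitability score. Each later epoch converts the best
  `urban_growth_rate`·(island cells) coastal arable/forest cells to
  built-up (suitability = −elevation − distance to existing built-up),
  never touching five interior reserve polygons; nothing else changes,
  so built-up is monotone and reserves are static.
- **Climate**: monthly precipitation follows fixed monsoon weights whose
  sum is exactly the annual layer. Annual precipitation = 1350 mm
  coastal base + 0.3 mm per m elevation (orographic) + a **mesoscale
  anomaly field generated on the coarse driver grid** (std 250 mm,
  persistent across epochs) + small fine-scale epoch noise, all times a
  per-epoch multiplier (CV 3 %; an optional mid-period bump raises the
  third epoch by 8 %). Temperature lapses −0.6 °C/100 m from a 24.5 °C
  coastal mean, ±4.5 °C seasonal cycle, 8 °C diurnal range. Radiation is
  a seasonal profile with small smoothed noise.
- **Soils and NDVI**: bulk density 1.25 ± 0.10 g cm⁻³ (clipped to
  0.9–1.6), coarse fragments increasing upslope (0–60 %), texture and
  organic carbon smooth fields. NDVI = class base value (forest 0.82 >
  grassland 0.74 > arable 0.68 > bareland 0.50 > built-up 0.45 > water
  0.15) + a small "vegetation condition" term + noise. Built-up NDVI is
  deliberately moderate: 30 m pixels of a humid tropical city contain
  substantial vegetation.
- **Driver stack** (12 layers at 50× the base cell, emulating ~4.6 km
  reanalysis over a 30 m analysis grid): PRE is the block-mean annual
  precipitation (tiny retrieval noise); PET from modified Hargreaves on
  the coarse temperatures; AET = min(c·PRE, PET) with a *spatially noisy*
  coefficient c; DEF = PET − AET exactly; RO = (noisy coefficient)·PRE ≤
  PRE; SOIL, VPD, SRAD, VS carry their structural parts plus independent
  noise; TMN/TMX have 0.4 °C retrieval noise; NDVI is the block-mean
  epoch-mean NDVI plus 0.02 compositing noise.

### The planted causal structure

Precipitation must be recoverable as the top driver of all four services
— that is the pipeline's parameter-recovery surface — so the generator
gives PRE three genuinely dominant channels: directly in the water
balance (P and R = c·P), through rainfall erosivity (∝ P^1.5) in RUSLE,
and through the CASA moisture scalar in NPP (hence also oxygen). In
addition a "vegetation condition" field mixes the standardized driver
fields into NDVI with configurable weights in which PRE is strictly the
maximum (validated at construction). Three structural choices keep the
recovery honest rather than fragile: the precipitation anomaly lives at
the driver grid's own scale, so the PRE layer observes it nearly
losslessly; the derived water-balance drivers (AET, RO, SOIL) carry
independent coefficient noise, so none is a linear copy of PRE; and the
island is a disk, so there are no flat off-cone corners whose slope
pattern temperature proxies could exploit. FPAR saturates at NDVI 0.65
(dense-canopy saturation), which keeps the productivity response from
being dominated by the land-class pattern that every elevation proxy
shares.

### What the generator does *not* emulate

Real geography and class nuance (paddy vs dry arable), TerraClimate's
physics, event-scale rainfall, soil–vegetation feedbacks, or any
observation operator beyond additive noise. Passing tests show the
algorithms are correct and the planted structure is recoverable; they do
not validate the service models against field data.

## Service models

- **Water retention** `Q = P − R − ET` (mm yr⁻¹). R uses per-class annual
  runoff coefficients (built-up 0.70, arable 0.40, forest 0.25, grassland
  0.30, water 0.05, bareland 0.55). ET = per-class cover coefficient ×
  Hargreaves PET (0.0023·Ra·(Tmean+17.8)·√(Tmax−Tmin), Ra from the
  standard solar-geometry closed form, summed monthly). Negative cells
  are retained, not clipped; `negative_fraction` reports their share
  (≈35 % of cells on the default island, mostly coastal arable).
- **Soil conservation** `A_SE = R·K·L·S·(1−C·P)` (t hm⁻² yr⁻¹ = t ha⁻¹
  yr⁻¹). R: Wischmeier monthly formula. K: EPIC texture/organic formula
  × 0.1317 (SI). S: 10.8 sinθ + 0.03 below 9 % slope, else 16.8 sinθ −
  0.5; slope from central differences. L = (λ/22.13)^m with
  m = β/(1+β), β = (sinθ/0.0896)/(3 sinθ^0.8 + 0.56); λ is a D8
  steepest-descent flow-path length seeded at one cell size and capped
  at 100 m, so a flat DEM gives L = 1 and S = 0.03. C = exp(−8·FVC)
  with FVC linear in NDVI between 0.10 and 0.80 (C = 1 bare, e⁻⁸ at
  full cover). P: per-class table with water at 0.
- **Carbon** `NEP = NPP − Rh`. NPP = SRAD·FPAR·0.5·ε with FPAR linear in
  NDVI between 0.10 and 0.65 clipped to [0, 0.95]; ε = 0.389·Ts1·Ts2·Wε
  g C MJ⁻¹, the standard temperature scalars around T_opt = 23 °C (the
  prevailing temperature of the island) and Wε = 0.5 + 0.5·(AET/PET)
  with AET = min(0.55·P, PET). Rs as printed above with P in m yr⁻¹ —
  the only unit reading that makes the 0.68 constant sensible — and δ
  read as the >2 mm coarse fraction. The empirical Rs is numerically
  tiny relative to this NPP (so NEP ≈ NPP); it is applied exactly as
  printed rather than re-scaled. Open water is excluded (nodata) from
  the carbon and oxygen layers: the productivity models describe
  terrestrial ecosystems.
- **Oxygen** `Q_O2 = 1.19·NPP`, the coefficient applied as stated
  without stoichiometric re-derivation.
- **Totals**: water Σ mm·cell m²·10⁻³ (reported 10⁹ m³); soil Σ t ha⁻¹ ·
  cell ha (10⁹ t); carbon/oxygen Σ g m⁻²·cell m²·10⁻⁶ (10⁶ t); change =
  last − first epoch.

## Landscape pattern and grain

Patches are 8-connected per-class components; perimeter counts cell
edges facing a different class, nodata or the map boundary (the boundary
counts as edge — ED and LSI depend on this and it is documented and
tested). Adjacencies for CONTAG/PLADJ use the double-count method; AI
uses single-count like adjacencies with the standard maximum-adjacency
formula (classes of a single cell contribute zero); IJI uses internal
class-to-class edge only. Undefined indices (CONTAG with one class, IJI
below three, PAFRAC below two patches) are NaN, never 0; SHEI of a
one-class map is 0. Every index is verified against an independent
loop-level oracle on >100 random maps.

CV = sample (n−1) standard deviation / mean × 100, computed on raw index
values across the grain series; indices with CV strictly above 5 % are
"sensitive" (a CV of exactly 5 % is not). The optimal grain is the first
interior point of a response curve whose second difference is
significant (above 5 % of the value range) after a flat stretch or a
sign flip — straight lines and constant-curvature series have none. The
procedure is verified on constructed curves with planted breakpoints;
on a given synthetic island the selected grain is whatever the SPLIT
curve produces (the real-data analysis this mirrors selected 110 m, a
value specific to that landscape and not asserted here). A `--year`
choice (or automatic max-mean-CV picker) selects the screening year.

## Change and trends

Transition matrices are exact cell cross-tabulations (areas in km²);
change ratio per class = (area_b − area_a)/island area × 100. Because
the ambiguity in "unchanged share" denominators, both changed/total and
unchanged/total are exposed. Per-pixel trends regress on epoch *index*
(epochs are unevenly spaced calendar years; switchable); |slope| within
1 % of the stack IQR classifies as stable. Zonal series use the final
epoch's built-up extent ("human disturbance zone") and the five reserve
polygons, with plain Pearson r against the island-wide mean series. On
the bump-enabled preset the urban-zone series correlates with the island
series at r > 0.5 for every service — the structural analogue, asserted
at that weaker truthful level, of the strong urban/island coherence the
motivating study reports.

## Driver ranking

n = 1000 cells sampled uniformly (optional minimum spacing) from the
cells valid in the response and all 12 aligned drivers; the response is
the multi-epoch mean service value (epoch-wise mode available). The
regression forest uses 500 trees, √p split candidates, and per-tree
bootstrap resamples of size 4/5·n drawn with replacement — reading the
"4/5 training, 1/5 out-of-bag" description as an approximate bootstrap;
rows absent from a tree's resample are its OOB set. OOB error is the
MSE of each row predicted only by trees for which it is OOB (rows never
OOB are excluded and counted). Importance = mean increase in OOB error
over seeded column permutations (default 10 repeats); ranks sort
descending with alphabetical tie-break. The forest is scikit-learn's;
the OOB error and permutation importance are computed here from the
per-tree in-bag indices. A classification-style binned-response mode is
deliberately out of scope: the responses are continuous, so regression
MSE replaces the misclassification rate.

Sampling happens at the 30 m analysis grid with drivers bilinearly
upsampled from the coarse grid — at desk scale the coarse grid has only
6×6 cells, far too few to sample directly.

## Problem sizes and tolerances

Default runs use the 300×300 island; tests use 100–120-cell grids where
the check is structural and the full default island where the check is
the parameter-recovery claim (20 independent worlds, n = 1000, 500
trees, 3 permutation repeats — repeats trade precision for runtime and
the top-rank outcome is insensitive beyond 3). Exact identities are
asserted to float round-off (rtol 1e−9–1e−12); stochastic recovery
claims are asserted at the rates stated in the tests (≥90 % of worlds,
≥80 % for top-2 weight order on planted tables). `run-all` writes CSVs
with a fixed float format; reruns with one config/seed are byte
identical.

## Known limitations

Water-retention runoff is an annual coefficient model (no routing or
curve numbers); the RUSLE flow path is single-direction D8 with a hard
cap; NPP has no soil-moisture bucket; Rs as printed yields values far
below NPP, making NEP ≈ NPP (retained as printed; config-escapable
grouping); the synthetic totals are toy-scale and only their units and
accounting are meaningful; permutation importance on correlated drivers
divides credit — the planted dominance is recovered because the
generator gives precipitation genuinely unique signal, not because the
estimator resolves collinearity.
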