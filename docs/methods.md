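# Methods

This note documents the models, parameter choices and known limitations of
the `nh3iam` pipeline in one place. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic study region

The region is a rectangular grid (default 36 × 36 cells of 0.74 Mha,
≈ 959 Mha total, cell (0,0) at the north-west) whose statistical structure —
not geography — matches what the downstream analysis needs:

* **Spatial autocorrelation.** Cropland, livestock and population intensity
  fields are white noise passed through repeated box blurs, squared to
  skew mass into a few hotspots. Only hotspot structure matters for the
  non-linear chemistry results; real administrative boundaries and land
  cover are deliberately out of scope.
* **Provinces and the pilot subset.** Provinces are a nearest-seed
  tessellation. Unless pinned in config, pilot provinces are the densest
  provinces accumulated until ≈ 20.8% of land area; cropland and livestock
  are then rescaled so pilot cells carry 54.7% of agricultural activity
  while national totals are conserved exactly (a feasibility check rejects
  configurations whose per-cell cropland caps cannot hold the national
  total).
* **Parcel histograms.** Cropland mass per cell is split over bins
  [0, 0.5, 1, 2, 5, 10, 50] ha by a truncated log-normal (median 0.41 ha,
  σ = 0.9), chosen so 80.8% of national cropland mass sits in sub-2-ha
  parcels. The 2 ha large-scale threshold is a bin edge, so consolidation
  never interpolates within a bin.
* **Slope.** Per-cell log-normal slopes are rescaled so the
  cropland-weighted share above 6° meets the configured 22.7% target
  (within ±2 percentage points by construction).
* **Farms.** Each cell's pig units split into a free-range aggregate point
  and large-scale point sources (mean 2 × 10⁶ pig units per point,
  Dirichlet-split, single dominant species, all above the per-species
  class thresholds: 500 swine, 100 dairy cattle, 200 beef cattle, 1500
  sheep/goats, 7500 layers, 30000 broilers). Species pig-unit shares
  (swine 0.35, dairy 0.10, beef 0.13, sheep/goats 0.12, layer 0.18,
  broiler 0.12) are package assumptions.
* **Meteorology.** Monthly temperature = national mean 13 °C + north–south
  gradient (±10 °C) + seasonal cosine (±12 °C, July peak); RH 0.62 ± 0.10.
  Daily series add a shared AR(1) synoptic anomaly (φ = 0.7) with a smooth
  per-cell amplitude; the unit-mean log-normal "stagnation" multiplier
  (σ = 0.45) scales monthly PM2.5 into daily values for polluted-day
  counting, making stagnation episodes spatially coherent.

What the generator does **not** emulate: real spatial covariance scales,
survey-based farm-size estimation, crop mix, or terrain-correlated
meteorology. Passing tests therefore demonstrate internal consistency of
the method chain under realistic *structure*, not predictive skill on real
Chinese data; the headline gridded magnitudes that depend on real geography
(e.g. regional PM2.5 decreases) are indicative only.

## Emission inventory

Emissions are EF × activity with NH3-N → NH3 fixed at 17/14.

* Fertilizer: rate × cropland × EF, EF = 0.15125 — a calibration constant
  reproducing the 4.9 Tg national sector total given the configured
  cropland and rates.
* Livestock: pig units × 7.2 kg N pu⁻¹ yr⁻¹ × per-stage volatilization
  fraction. Stage fractions are assumptions (not printed source values):
  free-range {grazing 0.24, spreading 0.22}, large-scale {housing 0.150,
  storage 0.090, spreading 0.118}. Their class-weighted mean (0.422)
  reproduces the 5.9 Tg sector total; the lower large-scale sum encodes
  better manure handling in confined systems, so the structural transition
  itself reduces emissions.
* Other (non-agricultural): one aggregate 2.0 Tg scalar allocated by
  population, aseasonal.
* Seasonality: monthly weights are modulated by exp(s·T′) with s = 0.04
  °C⁻¹ on the local monthly temperature anomaly and renormalized, so annual
  totals are exact and summer emissions exceed winter's (≈ 4.8 vs 1.7 Tg).
* Monte Carlo: each factor group (fertilizer EF, excretion N, each stage,
  other) gets an independent median-1 log-normal multiplier (GSDs 1.32,
  1.20, 1.15, 1.40 — assumptions); by linearity the national total is
  reassembled from sector subtotals, making 10⁴ draws cheap. Correlations
  between factors are not modelled (none are documented).

## Farm-structure transition

* **Consolidation** is a deterministic histogram merge: in cells with slope
  ≤ 6°, all sub-2-ha mass moves to the 2–5 ha bin; cropland is conserved
  exactly. This replaces survey-driven farm-size estimation while
  preserving the one quantity downstream stages consume (the large-scale
  share, 19.5% → 81.7% on the default region).
* **N rate** follows `rate′ = rate × (mean parcel size ratio)^ε` with
  ε = −0.29, floored at 80 kg N ha⁻¹. ε is calibrated so the national mean
  rate falls ≈ 31%, the figure the rate–size survey literature implies.
* **Livestock reallocation** moves a configured 88.5% of each province's
  free-range pig units to its large-scale farms proportionally to capacity
  (creating one seed farm when a province has none), conserving provincial
  totals exactly and yielding a 92.8% large-scale share. Proportional
  weights are a design choice; the source analysis does not state its
  allocation rule.

## Abatement scenarios

Technology measures apply `E_r = E(1 − a·η)` sequentially; demand-side
(food-waste) measures scale sectoral activity first with adoption 1.
Adoption `a` is resolved per cell: crop measures mix the smallholder
(0.222) and large-scale (0.438) survey rates by the local large-scale
parcel share; livestock measures mix 0.196/0.391 by each class's emission
share per stage (housing/storage purely large-scale, grazing purely
free-range). Measure efficiencies η are calibration constants back-derived
from the published per-measure national reduction rows given those adoption
rates and the baseline sector shares — the pipeline then *recomputes* the
rows (5.3, 2.7, 4.4, 2.2, 9.7, 10.6, 0.8, 1.3%) rather than storing them.
The manure-management η (0.815) is high because that measure spans the
entire waste chain.

Combined efficiencies use the multiplicative survival rule
`1 − Π(1 − η_i)`. The published combined scenario values use a
stream-specific accounting that is not recoverable (their own combined
figure differs from the sum of their rows), so only the scenario *ordering*
RFLW < TECH < NM < NMLF–PILOT < NMLF–ALL is asserted; the shipped
configuration computes 12.7 / 22.6 / 32.0 / 42.7 / 51.4%.

NMLF scenarios rebuild the inventory from the transitioned structure
(pilot-masked for NMLF–PILOT, with N management still applied nationwide).
Reallocation can raise emissions in receiving cells; scenario fields are
capped cell-wise at the baseline, interpreting relocated excess as locally
deposited near the new point sources — consistent with the plume-deposition
argument in the sub-grid experiment and required for the cell-wise
invariant 0 ≤ E_r ≤ E and a sign-definite PM response.

## Air quality

A one-box steady state per cell: gas concentration = emission flux ÷
dilution velocity (0.008 m s⁻¹) blended with 35% of the regional mean.
Sulfate, total nitrate and non-inorganic PM2.5 are ambient fields scaling
with population density (polluted-region co-location), with opposite
seasonal phases for sulfate (summer photochemistry) and nitrate/primary PM
(winter). Inorganic partitioning is sulfate-first neutralization (up to
2 NH4⁺ per SO4²⁻; bisulfate below that demand) plus NH4NO3 formation while
the NH3·HNO3 mixing-ratio product exceeds Kp(T, RH), with
ln Kp = 84.6 − 24220/T − 6.1 ln(T/298) (ppb²) and a linear suppression
above the 0.618 deliquescence RH. Total reduced N and total nitrate are
conserved to 1 × 10⁻⁹ relative. This preserves the NH3-rich/NH3-poor regime
distinction — the driver of every headline air-quality result — at the cost
of ignoring transport, organic/dust components and NH3 re-volatilization
after deposition (explicitly out of scope).

The sub-grid experiment packs a coarse cell's livestock NH3 flux into k of
100 five-km boxes. Within a box, NH3 above a local saturation (3 × the
stoichiometric demand of sulfate + nitrate) is lost to deposition in
competition with local ventilation (effective plume loss velocity
0.0005 m s⁻¹ vs 0.004 m s⁻¹ local dilution); surviving NH3 mixes before the
coarse-cell equilibrium. The metric — percentage underestimation of the
livestock PM2.5 contribution relative to the uniform spread — is therefore
exactly zero at k = 100 and at zero deposition velocity, and increases
monotonically as emissions concentrate (max ≈ 25% at k = 1 on defaults).
The experiment is validated by shape, not by a target value; no
parameterization of the original box model is published.

## Health

GEMM curves for COPD, lung cancer, IHD and stroke with a 2.4 µg m⁻³
counterfactual; θ, α, µ, ν per cause are external constants (Burnett et
al. 2018), collapsed to an all-age set (the default; an age-resolved mode
would only rescale θ and is not needed for scenario contrasts, which hold
population and baseline rates fixed across scenarios). Baseline
cause-specific mortality rates (COPD 6.5, lung cancer 4.6, IHD 12.4,
stroke 14.9 per 10⁴ person-years) are package assumptions of national
magnitude. Attributable deaths use 1 − 1/HR; avoided deaths are reference
minus scenario attributable deaths on annual-mean exposure.

## Economics

Ledger identity: net = private + societal − costs, exact before report
rounding (one decimal, US$ 2016 billions; ratios half-up to two decimals).
Line items at mid level are shipped as a data catalog (they are published
data, not model output), with two exceptions computed at run time: the two
large-scale capital items are stored as investments annualized at r = 0.05
over lt = 20 yr through the capital recovery factor (with the analytic
I/lt limit below r = 10⁻⁹), and the health item is avoided deaths ×
US$250,000. GHG benefits are mitigated Mt CO2e × US$50 t⁻¹. The
food-waste scenario's costs are *absent*, not zero — its ledger reports no
benefit–cost ratio. Low/high parameter levels are stub multipliers
(0.75/1.25, reversed for negative items so benefit levels are monotone
item-wise); only the mid level has published anchors.

## Numerical choices and degenerate inputs

* Grid size 36 × 36 (and 8–12 per side in tests) keeps the full pipeline
  under a minute while leaving ≥ 30 cells per province; cell area scales
  inversely with cell count so national totals stay attainable.
* Equilibrium quadratic solved in mixing-ratio space with clamping to
  [0, min(NH3, HNO3)]; responses are continuous and piecewise smooth.
* Empty masks, zero-cost ledgers, zero mean parcel sizes, unknown species/
  sectors/classes raise typed errors (`DomainError`, `ConfigurationError`,
  `AllocationError`) rather than propagating NaNs.
* All randomness flows from one seed via SHA-derived named substreams
  (< 2³¹); fixtures and pipeline outputs are byte-identical across runs.

## Known limitations

No atmospheric transport between cells beyond a single regional background
term; no soil/crop-specific EFs; no NH3 bidirectional exchange; adoption
rates enter as constants, not behavioral responses; the cost catalog's
low/high levels are placeholders; avoided-death magnitudes under the
large-scale scenarios are conservative relative to the source analysis
because the reduced-form chemistry understates hotspot PM2.5 responses.
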