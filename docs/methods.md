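# Methods

## Scope and design

The package computes biodiversity footprints of food in two driver
channels — agricultural land use and greenhouse-gas emissions — expressed
in a common unit (species × km², or range-fraction × km² for the
rarity-weighted metric) and routed through an environmentally extended
Leontief trade model. Everything upstream of the characterization factors
(the MRIO database, species range maps, land-use rasters, biome maps,
climate-model anomaly fields, land-use sensitivity coefficients) is
replaced by a synthetic world generator with known ground truth; the
package is therefore a *method* implementation validated by construction,
not an empirical analysis of the real economy.

## The synthetic world

One master seed drives everything; each generator draws from a named
substream (`SeedSequence([seed, crc32(name)])`), so adding a generator
never perturbs the draws of another, and every stage is a pure function of
(config, seed).

**Economy.** `generate_mrio` draws a nonnegative coefficient matrix with
region-major block structure. Cross-region blocks are scaled by
`trade_openness` ∈ [0, 1]; the whole matrix is then rescaled so its
spectral radius equals 0.85 × the configured bound (default bound 0.7),
keeping the economy strictly productive. Because the rescaling is a scalar
multiple, openness 0 leaves the cross-region blocks *exactly* zero.
Final demand per consuming region is sourced `(1 − openness)` domestically
plus an `openness`-scaled Dirichlet split over producers. The default
roster has five sectors — crops (cropland-using), livestock
(pasture-using), food processing, fertilizer, services — because that is
the minimal set that exercises every structural feature: two land-use
types, a purely downstream food product with zero direct land footprint,
a high-CO₂/N₂O industrial input, and a non-food rest-of-economy.

**Extensions.** Land intensities (km²/€1M) are lognormal around 2 (crops)
and 10 (pasture) km²/€1M — pasture-based production is roughly
five-fold more land-hungry, as in real land accounts. Emission intensities
(kg/€1M) are lognormal around sector-specific scales chosen for realism:
enteric methane dominates livestock (8e3 kg CH₄/€1M), fertilizer-driven
N₂O marks crops and fertilizer manufacture, CO₂ is universal (1e5–6e5
kg/€1M). These magnitudes are the study conditions of the synthetic world;
they are set once and not tuned.

**Species.** Range sizes are lognormal in cells (median 12, σ_log 1) —
the right-skew typical of real range-size distributions. Ranges are
contiguous near-square blocks; centres are drawn toward mid-grid rows so
richness shows a latitudinal gradient, and the smallest 30% of ranges
cluster near a few hotspot locations so rarity-weighted richness
concentrates regionally. Richness and rarity layers are produced by exact
stacking (count, and sum of inverse range areas).

**Landscape.** Regions are nearest-seed (Voronoi) territories; biomes are
latitude bands perturbed by smooth noise, mapped onto six biome groupings
from tropical forest to drylands; a smooth-noise threshold marks ~5% of
cells as an excluded biome which keeps its region but drops out of all
stratified statistics. One region and one biome per cell (dominant-class
rasterization; ties broken toward the lowest id by the argmin/floor
construction). Land-use fractions are smooth fields capped so the per-cell
sum stays ≤ 1.

**Climate.** Each of 4 synthetic climate models contributes a smooth
anomaly field around a 0.6 °C 20-year warming with 0.25 °C spread, clipped
at zero. The sensitivity surface H_x is a latitudinal loss rate: −0.008
per °C at the equator fading to a +0.002 per °C gain at the poles (warming
can add species at high latitudes, i.e. a negative loss), modulated ±20%
by smooth noise. If a metric lacks its own H_x the richness surface is
reused with a warning, mirroring the common situation where climate
sensitivities exist for vertebrate richness only.

**Grid.** Abstract equal-area cells (default 10-km resolution, 100 km²
per cell, 30×30). Spatial arithmetic only uses cell areas, so no
projection machinery is needed; grids are held in an xarray Dataset and
written as classic NetCDF.

## Characterization factors

**Land.** Stratum means S_{i,j,k} are weighted by land-use area
(fraction × cell area) by default: the CF should reflect the richness of
the land the land-use actually occupies, not an unweighted cell average.
A `weighted=False` switch gives plain cell means for comparison. S is
always the *pristine* richness layer — the quantity lost is the richness
the land would carry undisturbed. Biome shares B renormalise over covered
biomes, so excluded biomes leave both numerator and denominator. Strata
smaller than one cell of land-use area are flagged, never dropped
silently. Sensitivities P are negative for loss internally; the final CF
step flips sign so reported footprints are positive losses and genuine
gains arrive as negative CFs. The default P table is synthetic (tropical
biomes most sensitive, cropland worse than pasture); it is replaceable via
CSV (`SensitivityTable.from_csv`).

**GHG.** Warming per €1M uses absolute 20-year GTP coefficients (pulse
emission, not sustained or integrated): CO₂ 6.84e-16, CH₄ 4.62e-14, N₂O
1.89e-13 °C/kg, overridable for sensitivity analysis. The warming
weighting F_x is the multi-model mean anomaly normalised by its
area-weighted mean over the weighting domain — land-only by default
(switchable to all cells), recorded in the run manifest. The cell sum in
the CF is implemented twice — cell-wise and as the factorisation
CF = −ΔT × Σ_x F_x H_x S_x A_x — and the two are asserted equal to 1e-12
relative; the factorised form also makes the locational-independence
property explicit (identical emitters get identical CFs wherever they
are).

## Footprint accounting

`(I − A)⁻¹` is applied via dense LU solves; the explicit inverse is only
formed on request. Production footprints use direct territorial
attribution (intensity × gross output), so purely downstream products
(e.g. food processing) carry zero direct land footprint. Consumption
footprints keep two attribution views: by stressor origin (where the
impact physically occurs — used for %-imported and bilateral flows) and by
final product purchased (embodied intensity × demand). Both views sum to
the same regional totals; the bilateral flow matrix's row/column marginals
must match production/consumption totals to 1e-8 relative. Final-demand
categories are collapsed to one column per consuming region.

## Indicators

Net imports = consumption − production (sums to zero globally).
%-imported = 100 × (consumption − domestic flow)/consumption on the
stressor-origin view; undefined (zero-consumption) entries are flagged,
not silently infinite. Production is normalised per km² of territory,
consumption per capita; region areas are measured off the region grid and
populations drawn once from a named substream. The land:GHG ratio is
reported with its years-to-equal reading: at constant annual emissions, a
ratio of R means R years of emissions match the loss from all the land
conversion behind one year's production.

## What the synthetic world does and does not show

Passing tests demonstrate the *correctness of the accounting and CF
machinery*: conservation, linearity, duality, oracle equivalence, and
structural recoveries (autarky, forced importers). They do not calibrate
any real-world magnitude. In particular, the land:GHG ratio scales with
the total biodiversity-weighted area of the world (the GHG channel
integrates S_x A_x over every cell), so a 30×30 miniature world yields
ratios orders of magnitude larger than a planet-sized grid would; the
ratio's *accounting identity*, not its magnitude, is the testable claim at
this scale. Similarly, the gas split of the GHG footprint reflects the
synthetic emission scales, and %-imported reflects the chosen trade
openness.

## Numerical choices

- Spectral-radius target 0.85 × bound; a radius ≥ 1 raises
  `NonProductiveEconomyError` rather than producing garbage inverses.
- Biome-share sums are validated to 1e-10; warming-weight means to 1e-10;
  marginal consistency to 1e-8 relative; kernel duality to 1e-12 relative.
- Degenerate inputs fail loudly: zero global-mean anomaly, missing
  sensitivity entries (named pair), unknown gases, zero/missing population
  or area (named region), misaligned labels.
- Determinism is bit-level: two runs of one config write byte-identical
  CSV/NetCDF bundles (no timestamps anywhere in outputs).

## Problem sizes

Default study conditions: 4 regions × 5 sectors, 30×30 grid, 300 species,
4 climate models. Oracle suites use up to 10 regions × 6 sectors
(economies), ten 30×30 worlds (land CFs) and 50×50 grids (range
stacking). These sizes fully exercise every code path while keeping the
whole suite and the acceptance script in seconds.

## Known limitations

- The synthetic economy has no supply-use structure, price layers or
  multiple final-demand categories.
- Ranges are rectangular blocks; real range geometries, elevational
  filtering and seasonal occupancy are not emulated.
- Mixed-cell region/biome membership is not represented (dominant class
  only).
- The land-use sensitivity table and climate-sensitivity surface are
  synthetic placeholders with realistic structure, not fitted estimates;
  conclusions about real regions or products cannot be drawn from the
  default world.
- Emissions from land clearance are excluded from the GHG channel by
  design; the GHG footprint covers one year's production emissions only.
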