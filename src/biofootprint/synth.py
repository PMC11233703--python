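"""Synthetic world generator: a miniature economy, biosphere and climate.

Stands in for the real study inputs (a global MRIO database, species range
maps, crop/pasture rasters, biome maps, climate-model anomaly fields) with
a self-consistent generated world whose ground truth is known exactly:

- a productive multi-regional economy (spectral radius of A bounded away
  from 1) with tunable trade openness, and physical extensions per €1M
  (agricultural land by land-use type; CO₂/CH₄/N₂O emissions);
- species ranges drawn with a right-skewed (lognormal) size distribution,
  centred preferentially at low latitudes so richness shows a latitudinal
  gradient and narrow-ranged species cluster in endemism hotspots;
- a landscape of trade regions and biomes (one of each per cell, with an
  excluded-biome mask) and smooth land-use fraction fields;
- climate-model warming anomalies (smooth, spatially heterogeneous) and a
  climate-sensitivity grid H_x (richness change per °C, more negative in
  species-rich low latitudes; gains possible at high latitudes).

Every generator is a pure function of (config, seed).  Sub-generators draw
from named substreams of a single master seed, so adding one generator does
not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage

from .mrio import ExtensionTable, MRIOSystem, SectorSpec, spectral_radius
from .world import (
    EXCLUDED_BIOME,
    NO_REGION,
    GridSpec,
    SpeciesRange,
    WorldGrids,
    stack_ranges,
)

GASES = ["co2", "ch4", "n2o"]

#: default sector roster: two land-using food sectors (the agricultural
#: products carrying cropland and pasture), downstream food processing,
#: fertilizer manufacture, and a non-food rest-of-economy sector.
DEFAULT_SECTORS = [
    SectorSpec("crops", food=True, landuse="cropland"),
    SectorSpec("livestock", food=True, landuse="pasture"),
    SectorSpec("food_processing", food=True),
    SectorSpec("fertilizer", food=True),
    SectorSpec("services", food=False),
]

#: emission-intensity scales, kg per €1M of output, loosely calibrated to
#: the magnitudes of agricultural emission accounts: livestock dominated by
#: enteric methane, crops by fertiliser-driven N₂O, everything by some CO₂.
_EMISSION_SCALE = {
    "crops": {"co2": 1.5e5, "ch4": 2.0e3, "n2o": 6.0e2},
    "livestock": {"co2": 2.0e5, "ch4": 8.0e3, "n2o": 3.0e2},
    "food_processing": {"co2": 3.0e5, "ch4": 2.0e2, "n2o": 2.0e1},
    "fertilizer": {"co2": 6.0e5, "ch4": 1.0e2, "n2o": 1.2e3},
    "services": {"co2": 1.0e5, "ch4": 5.0e1, "n2o": 1.0e1},
}
_DEFAULT_EMISSION_SCALE = {"co2": 2.0e5, "ch4": 5.0e2, "n2o": 1.0e2}

#: land-area intensity scale, km² per €1M, by land-use type (pasture-based
#: production is markedly more land-hungry than cropping).
_LAND_SCALE = {"cropland": 2.0, "pasture": 10.0}


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, independent random substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# economy
# ---------------------------------------------------------------------------


def generate_mrio(
    n_regions: int,
    sectors: list[SectorSpec] | None = None,
    trade_openness: float = 0.3,
    seed: int = 0,
    spectral_bound: float = 0.7,
) -> tuple[MRIOSystem, ExtensionTable]:
    """Generate a productive multi-regional economy with extensions.

    ``trade_openness`` in [0, 1] controls both intermediate trade (the
    cross-region blocks of A) and final-demand import sourcing; 0 yields a
    strictly autarkic world (block-diagonal A, purely domestic sourcing).
    The technical-coefficient matrix is rescaled so its spectral radius sits
    at 0.85 × ``spectral_bound``, strictly inside the productive regime.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    if not 0.0 <= trade_openness <= 1.0:
        raise ValueError(f"trade_openness must lie in [0, 1], got {trade_openness}")
    sectors = list(sectors) if sectors is not None else list(DEFAULT_SECTORS)
    if not sectors:
        raise ValueError("need at least one sector")
    if not any(s.food for s in sectors):
        raise ValueError("sector spec names no food-related sector")
    if not any(s.landuse for s in sectors):
        raise ValueError("sector spec names no land-using sector")

    rng = substream(seed, "mrio")
    n_sec = len(sectors)
    regions = [f"R{i:02d}" for i in range(n_regions)]
    n = n_regions * n_sec

    # intra- and inter-regional coefficient blocks; openness scales trade
    A = rng.gamma(shape=1.5, scale=1.0, size=(n, n))
    for r in range(n_regions):
        for s in range(n_regions):
            blk = (slice(r * n_sec, (r + 1) * n_sec), slice(s * n_sec, (s + 1) * n_sec))
            if r != s:
                A[blk] *= trade_openness * 0.3
    rho = spectral_radius(A)
    A *= 0.85 * spectral_bound / rho

    # final demand: size per (sector, consumer), sourced across producers
    demand_scale = np.where([s.food for s in sectors], 200.0, 500.0)  # €1M
    Y = np.zeros((n, n_regions))
    for r in range(n_regions):  # consuming region
        size = demand_scale * rng.lognormal(mean=0.0, sigma=0.4, size=n_sec)
        shares = rng.dirichlet(np.full(n_regions, 2.0))
        for k in range(n_regions):  # producing region
            src = (1.0 - trade_openness) * (1.0 if k == r else 0.0) + trade_openness * shares[k]
            Y[k * n_sec : (k + 1) * n_sec, r] = size * src

    system = MRIOSystem(regions=regions, sectors=sectors, A=A, Y=Y)

    # extensions per €1M output
    idx = system.index
    landuse_types = sorted({s.landuse for s in sectors if s.landuse})
    land = pd.DataFrame(0.0, index=idx, columns=landuse_types)
    emis = pd.DataFrame(0.0, index=idx, columns=GASES)
    for region in regions:
        for s in sectors:
            row = (region, s.name)
            if s.landuse:
                scale = _LAND_SCALE.get(s.landuse, 3.0)
                land.loc[row, s.landuse] = scale * rng.lognormal(mean=0.0, sigma=0.5)
            scales = _EMISSION_SCALE.get(s.name, _DEFAULT_EMISSION_SCALE)
            for g in GASES:
                emis.loc[row, g] = scales[g] * rng.lognormal(mean=0.0, sigma=0.4)
    return system, ExtensionTable(land_area=land, emissions=emis)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """White noise blurred to a smooth field, rescaled to zero mean, unit sd."""
    f = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def generate_landscape(
    grid: GridSpec,
    n_biomes: int = 4,
    n_regions: int = 3,
    landuse_types: list[str] | None = None,
    seed: int = 0,
    excluded_fraction: float = 0.05,
) -> WorldGrids:
    """Partition the grid into trade regions and biomes; lay down land use.

    Regions are nearest-seed (Voronoi) territories, so they are contiguous.
    Biomes follow latitude bands perturbed by smooth noise, mimicking the
    coarse biome groupings (tropical forest near the equator, temperate /
    boreal classes poleward).  A smooth-noise threshold marks a fraction of
    cells as an excluded biome (the analogue of tundra, mangroves, rock &
    ice being masked out); those cells keep their region but drop out of
    every stratified statistic.  Land-use fractions are smooth fields in
    [0, 1], jointly rescaled where they would overfill a cell.
    """
    if n_regions < 1 or n_biomes < 1:
        raise ValueError("need at least one region and one biome")
    landuse_types = list(landuse_types) if landuse_types is not None else ["cropland", "pasture"]

    rng = substream(seed, "landscape")
    ny, nx = grid.ny, grid.nx
    yy, xx = np.mgrid[0:ny, 0:nx]

    # regions: Voronoi around random seed points; ties go to the lowest id
    seeds_y = rng.uniform(0, ny, size=n_regions)
    seeds_x = rng.uniform(0, nx, size=n_regions)
    d2 = (yy[None] - seeds_y[:, None, None]) ** 2 + (xx[None] - seeds_x[:, None, None]) ** 2
    region_id = np.argmin(d2, axis=0).astype(np.int32)

    # biomes: latitude bands + smooth perturbation, lowest-id tie-break via floor
    lat = yy / max(ny - 1, 1)  # 0 at top row, 1 at bottom
    band = lat * n_biomes + 0.8 * _smooth_field(rng, (ny, nx), sigma=max(ny, nx) / 10)
    biome_id = np.clip(np.floor(band), 0, n_biomes - 1).astype(np.int32)

    # excluded-biome mask (spatially clumped)
    if excluded_fraction > 0:
        noise = _smooth_field(rng, (ny, nx), sigma=max(ny, nx) / 12)
        thresh = np.quantile(noise, 1.0 - excluded_fraction)
        biome_id[noise > thresh] = EXCLUDED_BIOME

    # land-use fractions: smooth nonnegative fields, capped so Σ_i ≤ 1
    fracs = np.empty((len(landuse_types), ny, nx))
    for i in range(len(landuse_types)):
        f = _smooth_field(rng, (ny, nx), sigma=max(ny, nx) / 8)
        fracs[i] = np.clip(0.25 + 0.25 * f, 0.0, 1.0)
    total = fracs.sum(axis=0)
    over = total > 0.95
    if over.any():
        fracs[:, over] *= 0.95 / total[over]

    import xarray as xr

    ds = xr.Dataset(
        {
            "region_id": (("y", "x"), region_id),
            "biome_id": (("y", "x"), biome_id),
            "landuse_fraction": (("landuse", "y", "x"), fracs),
        },
        coords={"landuse": landuse_types},
        attrs={"cell_area": grid.cell_area},
    )
    grids = WorldGrids(ds, grid.cell_area)
    grids.validate()
    return grids


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangeSizeDistribution:
    """Lognormal range-size model, in cells (right-skewed, as real range-size
    distributions are); ``hotspot_quantile`` sends the smallest-ranged
    species to a few endemism hotspots instead of anywhere on the latitude
    gradient."""

    median_cells: float = 12.0
    sigma_log: float = 1.0
    hotspot_quantile: float = 0.3

    def sample_cells(self, rng: np.random.Generator, n: int, n_cells: int) -> np.ndarray:
        sizes = rng.lognormal(mean=np.log(self.median_cells), sigma=self.sigma_log, size=n)
        return np.clip(np.round(sizes), 1, n_cells).astype(int)


def generate_species_ranges(
    n_species: int,
    grid: GridSpec,
    distribution: RangeSizeDistribution | None = None,
    seed: int = 0,
) -> list[SpeciesRange]:
    """Draw species ranges as contiguous near-square blocks on the grid.

    Range centres are biased toward mid-grid rows (the 'equator'), giving a
    latitudinal richness gradient; the smallest-ranged species are placed
    near a handful of hotspot locations so rarity-weighted richness
    concentrates in some regions, as it does in reality.
    """
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    if n_species < 0:
        raise ValueError("n_species must be ≥ 0")
    dist = distribution or RangeSizeDistribution()
    rng = substream(seed, "species")
    ny, nx = grid.ny, grid.nx

    sizes = dist.sample_cells(rng, n_species, grid.n_cells)
    small_cut = np.quantile(sizes, dist.hotspot_quantile) if n_species else 0
    n_hotspots = max(1, min(3, ny * nx // 100 + 1))
    hotspots = np.column_stack(
        [
            np.clip(rng.normal(ny / 2, ny / 6, size=n_hotspots), 0, ny - 1),
            rng.uniform(0, nx, size=n_hotspots),
        ]
    )

    ranges: list[SpeciesRange] = []
    for sp in range(n_species):
        size = int(sizes[sp])
        if size <= small_cut and n_hotspots:
            hy, hx = hotspots[rng.integers(n_hotspots)]
            cy = int(np.clip(rng.normal(hy, ny / 20), 0, ny - 1))
            cx = int(np.clip(rng.normal(hx, nx / 20), 0, nx - 1))
        else:
            cy = int(np.clip(rng.normal(ny / 2, ny / 4), 0, ny - 1))
            cx = int(rng.integers(nx))
        # near-square block of ~size cells around (cy, cx), clipped to grid
        h = max(1, int(round(np.sqrt(size))))
        w = max(1, int(np.ceil(size / h)))
        y0 = int(np.clip(cy - h // 2, 0, max(ny - h, 0)))
        x0 = int(np.clip(cx - w // 2, 0, max(nx - w, 0)))
        y1, x1 = min(y0 + h, ny), min(x0 + w, nx)
        block_y, block_x = np.mgrid[y0:y1, x0:x1]
        cells = (block_y * nx + block_x).ravel()
        ranges.append(SpeciesRange(species_id=sp, cells=cells, cell_area=grid.cell_area))
    return ranges


def add_biodiversity_layers(
    grids: WorldGrids, ranges: list[SpeciesRange], grid: GridSpec
) -> WorldGrids:
    """Stack ranges into richness and rarity layers on an existing world."""
    richness, rarity = stack_ranges(ranges, grid)
    grids.ds["richness"] = (("y", "x"), richness)
    grids.ds["rarity"] = (("y", "x"), rarity)
    return grids


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivitySpec:
    """Climate-sensitivity grid model H_x (proportional richness change per °C).

    ``constant`` pins H_x everywhere (useful for analytic checks); otherwise
    H_x is a latitude-dependent loss rate — strongest at the species-rich low
    latitudes, fading poleward and crossing into small gains (negative loss)
    at the highest latitudes where warming can add species.
    """

    constant: float | None = None
    base: float = -0.008  # per °C, at the equator
    polar_gain: float = 0.002  # per °C, at the poles

    def build(self, rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
        if self.constant is not None:
            return np.full(shape, self.constant)
        ny, nx = shape
        lat = np.abs(np.linspace(-1.0, 1.0, ny))[:, None]  # 0 equator, 1 poles
        h = self.base * (1.0 - lat) + self.polar_gain * lat
        h = h * (1.0 + 0.2 * _smooth_field(rng, shape, sigma=max(ny, nx) / 10))
        return h


def generate_climate(
    grids: WorldGrids,
    n_models: int = 4,
    warming_mean: float = 0.6,
    warming_spread: float = 0.25,
    sensitivity: SensitivitySpec | dict[str, SensitivitySpec] | None = None,
    seed: int = 0,
) -> WorldGrids:
    """Attach per-model warming anomalies and climate-sensitivity grids.

    Each climate model contributes a smooth anomaly field around
    ``warming_mean`` °C (the projected 20-year warming) with inter-model and
    spatial spread ``warming_spread``; anomalies are clipped at 0 (no
    cooling cells, keeping the global-mean denominator well-behaved).
    ``sensitivity`` maps metric name → spec; a single spec is shared.
    """
    if n_models < 1:
        raise ValueError("need at least one climate model")
    rng = substream(seed, "climate")
    ny, nx = grids.shape

    anomalies = np.empty((n_models, ny, nx))
    for m in range(n_models):
        offset = rng.normal(0.0, warming_spread / 2)
        fields = _smooth_field(rng, (ny, nx), sigma=max(ny, nx) / 6)
        anomalies[m] = np.clip(warming_mean + offset + warming_spread * fields, 0.0, None)

    if sensitivity is None:
        sensitivity = SensitivitySpec()
    if isinstance(sensitivity, SensitivitySpec):
        sens_map = {"richness": sensitivity, "rarity": sensitivity}
    else:
        sens_map = dict(sensitivity)
    metrics = list(sens_map)
    sens = np.stack([sens_map[m].build(rng, (ny, nx)) for m in metrics])

    grids.ds["anomaly"] = (("model", "y", "x"), anomalies)
    grids.ds["sensitivity"] = (("metric", "y", "x"), sens)
    grids.ds = grids.ds.assign_coords(
        model=[f"climate_model_{m}" for m in range(n_models)], metric=metrics
    )
    return grids


# ---------------------------------------------------------------------------
# whole-world convenience
# ---------------------------------------------------------------------------


@dataclass
class WorldConfig:
    """Everything needed to generate one synthetic world, reproducibly."""

    seed: int = 0
    ny: int = 30
    nx: int = 30
    cell_area: float = 100.0  # km² — a 10 km equal-area grid
    n_regions: int = 4
    n_biomes: int = 4
    n_species: int = 300
    trade_openness: float = 0.3
    spectral_bound: float = 0.7
    excluded_fraction: float = 0.05
    n_climate_models: int = 4
    warming_mean: float = 0.6  # °C over the 20-year horizon
    warming_spread: float = 0.25
    sectors: list[SectorSpec] = field(default_factory=lambda: list(DEFAULT_SECTORS))
    range_distribution: RangeSizeDistribution = field(default_factory=RangeSizeDistribution)
    sensitivity: SensitivitySpec = field(default_factory=SensitivitySpec)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.ny, self.nx, self.cell_area)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    system: MRIOSystem
    extensions: ExtensionTable
    grids: WorldGrids
    ranges: list[SpeciesRange]


def generate_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Generate the full synthetic world from one config + master seed."""
    cfg = config or WorldConfig()
    system, extensions = generate_mrio(
        cfg.n_regions,
        cfg.sectors,
        trade_openness=cfg.trade_openness,
        seed=cfg.seed,
        spectral_bound=cfg.spectral_bound,
    )
    landuse_types = sorted({s.landuse for s in cfg.sectors if s.landuse})
    grids = generate_landscape(
        cfg.grid,
        n_biomes=cfg.n_biomes,
        n_regions=cfg.n_regions,
        landuse_types=landuse_types,
        seed=cfg.seed,
        excluded_fraction=cfg.excluded_fraction,
    )
    ranges = generate_species_ranges(
        cfg.n_species, cfg.grid, distribution=cfg.range_distribution, seed=cfg.seed
    )
    add_biodiversity_layers(grids, ranges, cfg.grid)
    generate_climate(
        grids,
        n_models=cfg.n_climate_models,
        warming_mean=cfg.warming_mean,
        warming_spread=cfg.warming_spread,
        sensitivity=cfg.sensitivity,
        seed=cfg.seed,
    )
    # region labels on the grid correspond to MRIO regions by id
    return SyntheticWorld(cfg, system, extensions, grids, ranges)
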