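"""Gridded world containers: equal-area grid, species ranges, stacked layers.

The spatial model is an abstract equal-area grid (constant cell area in km²)
rather than a projected raster: all downstream arithmetic — zonal means,
biome shares, climate weighting — only needs cell areas, not coordinates.
Layers are held in an :class:`xarray.Dataset` so they stay co-registered and
can be round-tripped through NetCDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

#: biome code marking cells excluded from all stratified statistics
#: (the analogue of tundra / mangroves / flooded grassland / rock & ice
#: being dropped from the biome groupings).
EXCLUDED_BIOME = -1

#: region code for cells outside any trade region (ocean / no-data).
NO_REGION = -1


@dataclass(frozen=True)
class GridSpec:
    """Shape and cell area of the equal-area analysis grid."""

    ny: int
    nx: int
    cell_area: float  # km² per cell, constant

    def __post_init__(self) -> None:
        if self.ny < 1 or self.nx < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def n_cells(self) -> int:
        return self.ny * self.nx


@dataclass(frozen=True)
class SpeciesRange:
    """A species' occupied cells on the grid.

    ``cells`` are flat indices (row-major) into the grid; the range is a
    contiguous block by construction of the generator.  ``range_area`` is
    derived: occupied-cell count × cell area.
    """

    species_id: int
    cells: np.ndarray = field(repr=False)
    cell_area: float

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise ValueError(f"species {self.species_id} has an empty range")

    @property
    def range_area(self) -> float:
        return float(len(self.cells)) * self.cell_area


class WorldGrids:
    """Co-registered equal-area layers for one synthetic (or real) world.

    Variables on dims ``(y, x)`` unless noted:

    - ``region_id``    int, trade region per cell (``NO_REGION`` = masked)
    - ``biome_id``     int, biome grouping (``EXCLUDED_BIOME`` = masked biome)
    - ``landuse_fraction``  (landuse, y, x), fraction of cell in each land-use
    - ``richness``     species per cell (S_x), pristine baseline
    - ``rarity``       rarity-weighted richness (sum of inverse range areas)
    - ``anomaly``      (model, y, x), projected warming ΔT_x in °C
    - ``sensitivity``  (metric, y, x), proportional richness change per °C (H_x)
    """

    def __init__(self, ds: xr.Dataset, cell_area: float):
        if cell_area <= 0:
            raise ValueError("cell_area must be positive")
        self.ds = ds
        self.cell_area = float(cell_area)

    # -- construction -------------------------------------------------

    @classmethod
    def empty(cls, spec: GridSpec) -> "WorldGrids":
        shape = (spec.ny, spec.nx)
        ds = xr.Dataset(
            {
                "region_id": (("y", "x"), np.full(shape, NO_REGION, dtype=np.int32)),
                "biome_id": (("y", "x"), np.full(shape, EXCLUDED_BIOME, dtype=np.int32)),
            },
            attrs={"cell_area": spec.cell_area},
        )
        return cls(ds, spec.cell_area)

    # -- basic geometry ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.ds.sizes["y"], self.ds.sizes["x"]

    @property
    def n_cells(self) -> int:
        ny, nx = self.shape
        return ny * nx

    @property
    def unmasked(self) -> np.ndarray:
        """Cells carrying both a trade region and a non-excluded biome."""
        return (self.ds["region_id"].values != NO_REGION) & (
            self.ds["biome_id"].values != EXCLUDED_BIOME
        )

    @property
    def land(self) -> np.ndarray:
        """Cells belonging to any trade region (masked biomes included)."""
        return self.ds["region_id"].values != NO_REGION

    # -- layer access ----------------------------------------------------

    def layer(self, name: str) -> np.ndarray:
        return self.ds[name].values

    def metric_layer(self, metric: str) -> np.ndarray:
        """Richness layer for a biodiversity metric ('richness' | 'rarity')."""
        if metric not in ("richness", "rarity"):
            raise KeyError(f"unknown biodiversity metric {metric!r}")
        if metric not in self.ds:
            raise KeyError(f"metric layer {metric!r} not present in grids")
        return self.ds[metric].values

    def landuse_types(self) -> list[str]:
        return [str(v) for v in self.ds["landuse"].values]

    def landuse_fraction(self, landuse: str) -> np.ndarray:
        return self.ds["landuse_fraction"].sel(landuse=landuse).values

    def sensitivity_layer(self, metric: str) -> np.ndarray:
        """H_x grid for a metric; falls back to the richness grid with a warning.

        Mirrors the situation where climate sensitivities exist for species
        richness (vertebrates) only: the rarity pipeline reuses them.
        """
        metrics = [str(m) for m in self.ds["metric"].values]
        if metric in metrics:
            return self.ds["sensitivity"].sel(metric=metric).values
        if "richness" in metrics:
            import warnings

            warnings.warn(
                f"no climate-sensitivity grid for metric {metric!r}; "
                "reusing the species-richness sensitivity grid",
                stacklevel=2,
            )
            return self.ds["sensitivity"].sel(metric="richness").values
        raise KeyError(f"no climate-sensitivity grid available for {metric!r}")

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if "landuse_fraction" in self.ds:
            frac = self.ds["landuse_fraction"].values
            if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
                raise ValueError("land-use fractions must lie in [0, 1]")
            if np.any(frac.sum(axis=0) > 1 + 1e-9):
                raise ValueError("per-cell land-use fractions must sum to ≤ 1")
        for name in ("richness", "rarity"):
            if name in self.ds and np.any(self.ds[name].values < 0):
                raise ValueError(f"{name} layer must be nonnegative")

    # -- i/o -----------------------------------------------------------

    def to_netcdf(self, path) -> None:
        # NetCDF3 via the scipy engine: no string coords, encode as attrs
        ds = self.ds.copy()
        for coord in ("landuse", "metric", "model"):
            if coord in ds.coords:
                ds.attrs[f"{coord}_names"] = ",".join(str(v) for v in ds[coord].values)
                ds = ds.assign_coords({coord: np.arange(ds.sizes[coord])})
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "WorldGrids":
        ds = xr.load_dataset(path, engine="scipy")
        for coord in ("landuse", "metric", "model"):
            key = f"{coord}_names"
            if key in ds.attrs:
                ds = ds.assign_coords({coord: ds.attrs[key].split(",")})
                del ds.attrs[key]
        return cls(ds, float(ds.attrs["cell_area"]))


def stack_ranges(ranges: list[SpeciesRange], grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stack species ranges into richness and rarity-weighted richness layers.

    richness(x) = number of species whose range covers cell x;
    rarity(x)   = Σ over those species of 1 / range_area, so narrow-ranged
    species dominate the layer where they occur.
    """
    richness = np.zeros(grid.n_cells, dtype=float)
    rarity = np.zeros(grid.n_cells, dtype=float)
    for rng in ranges:
        np.add.at(richness, rng.cells, 1.0)
        np.add.at(rarity, rng.cells, 1.0 / rng.range_area)
    return richness.reshape(grid.ny, grid.nx), rarity.reshape(grid.ny, grid.nx)
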