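"""Environmentally extended Leontief engine.

The economy is the standard multi-regional input-output (MRIO) model: a
technical-coefficient matrix ``A`` (€ of input per € of output, indexed
region-major by (region, sector)), final demand ``Y`` (one column per
consuming region, €1M) and gross output ``x`` satisfying ``x = A·x + y``.
Footprints follow the environmentally extended Leontief model

    E = f · (I − A)⁻¹ · Y

with ``f`` a direct-intensity vector (stressor per €1M of output).  All
solves go through a dense LU factorisation of ``I − A``; the explicit
inverse is only materialised where a caller asks for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg


class NonProductiveEconomyError(ValueError):
    """Raised when the spectral radius of A is ≥ 1 (economy not productive)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorSpec:
    """One economic sector: name, whether food-related, which land-use it uses.

    ``landuse`` is None for sectors that occupy no agricultural land
    (processing, manufacturing, services); for land-using sectors it names
    the land-use type whose area intensity the sector carries.
    """

    name: str
    food: bool = False
    landuse: str | None = None


@dataclass
class MRIOSystem:
    """An MRIO economy: labels, coefficients, final demand, gross output."""

    regions: list[str]
    sectors: list[SectorSpec]
    A: np.ndarray  # (n, n), n = len(regions) * len(sectors), region-major
    Y: np.ndarray  # (n, n_regions)
    x: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.regions) * len(self.sectors)
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}×{n} (region-major), got {self.A.shape}")
        if self.Y.shape != (n, len(self.regions)):
            raise ValueError(f"Y must be {n}×{len(self.regions)}, got {self.Y.shape}")
        if np.any(self.A < 0) or np.any(self.Y < 0):
            raise ValueError("A and Y must be nonnegative")
        if self.x is None:
            self.x = gross_output(self.A, self.Y)

    @property
    def n(self) -> int:
        return len(self.regions) * len(self.sectors)

    @property
    def index(self) -> pd.MultiIndex:
        """Region-major (region, sector) labels for rows/columns of A."""
        return pd.MultiIndex.from_product(
            [self.regions, [s.name for s in self.sectors]], names=["region", "sector"]
        )

    @property
    def sector_names(self) -> list[str]:
        return [s.name for s in self.sectors]

    def food_mask(self) -> np.ndarray:
        """Boolean over the (region, sector) axis marking food-related sectors."""
        per_sector = np.array([s.food for s in self.sectors], dtype=bool)
        return np.tile(per_sector, len(self.regions))


@dataclass
class ExtensionTable:
    """Physical stressors per €1M of output for each (region, sector).

    ``land_area``: km² of each land-use type occupied per €1M of output,
    indexed (region, sector) × land-use type — nonzero only for land-using
    sectors.  ``emissions``: kg of each greenhouse gas emitted per €1M,
    indexed (region, sector) × gas.
    """

    land_area: pd.DataFrame
    emissions: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.land_area.values < 0).any():
            raise ValueError("land-area intensities must be nonnegative")
        if (self.emissions.values < 0).any():
            raise ValueError("emission intensities must be nonnegative")

    @property
    def landuse_types(self) -> list[str]:
        return list(self.land_area.columns)

    @property
    def gases(self) -> list[str]:
        return list(self.emissions.columns)


# ---------------------------------------------------------------------------
# core linear algebra
# ---------------------------------------------------------------------------


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _check_productive(A: np.ndarray) -> None:
    if A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if np.any(A < 0):
        raise ValueError("A must be nonnegative")
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise NonProductiveEconomyError(
            f"economy not productive: spectral radius of A is {rho:.6f} ≥ 1"
        )


def leontief_inverse(A: np.ndarray) -> np.ndarray:
    """(I − A)⁻¹, the total-requirements matrix.

    Requires a productive economy (spectral radius < 1), which also
    guarantees the inverse is nonnegative (Neumann series of a nonnegative
    matrix).
    """
    _check_productive(A)
    eye = np.eye(A.shape[0])
    return scipy.linalg.solve(eye - A, eye)


def leontief_apply(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve (I − A) X = B — the Leontief inverse applied without forming it."""
    _check_productive(A)
    return scipy.linalg.solve(np.eye(A.shape[0]) - A, B)


def gross_output(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Gross output x = (I − A)⁻¹ · y with y the row-sums of final demand."""
    y = Y.sum(axis=1) if Y.ndim == 2 else np.asarray(Y, dtype=float)
    return leontief_apply(A, y)


# ---------------------------------------------------------------------------
# footprint accounting
# ---------------------------------------------------------------------------


def production_footprints(f: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Territorial (production-based) footprint per (region, sector).

    Direct attribution: stressor intensity × gross output, so impacts sit
    with the producing sector on whose territory they physically occur.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != x.shape:
        raise ValueError(f"intensity vector {f.shape} does not align with output {x.shape}")
    return f * x


def consumption_footprints(
    f: np.ndarray, A: np.ndarray, Y: np.ndarray, *, by: str = "origin"
) -> np.ndarray:
    """Consumption-based footprints E = f · (I − A)⁻¹ · Y, disaggregated.

    ``by='origin'`` keeps the producing (region, sector) where the stressor
    physically occurs: returns diag(f) · L · Y, shape (n, n_regions); column
    sums are the regions' consumption footprints.

    ``by='product'`` attributes to the final product purchased: returns
    (f·L) ∘ Y, i.e. the embodied intensity of each final product times the
    demand for it.  Column sums agree between the two views.
    """
    f = np.asarray(f, dtype=float)
    if by == "origin":
        LY = leontief_apply(A, Y)
        return f[:, None] * LY
    if by == "product":
        m = leontief_apply(A.T, f).T  # f · L  via  Lᵀ fᵀ
        return m[:, None] * Y
    raise ValueError(f"unknown attribution view {by!r}")


def bilateral_decomposition(
    f: np.ndarray, A: np.ndarray, Y: np.ndarray, n_regions: int
) -> np.ndarray:
    """Embodied flows E[s, r]: impact occurring in producing region s that is
    driven by region r's final demand.  Row sums equal production footprints
    by region; column sums equal consumption footprints by region.
    """
    by_origin = consumption_footprints(f, A, Y, by="origin")
    n = by_origin.shape[0]
    if n % n_regions:
        raise ValueError("rows of A do not divide evenly into regions")
    per_region = n // n_regions
    return by_origin.reshape(n_regions, per_region, n_regions).sum(axis=1)


# ---------------------------------------------------------------------------
# labelled footprint container
# ---------------------------------------------------------------------------


@dataclass
class FootprintTensor:
    """Footprints for one stressor metric (and gas/land component).

    ``by_origin``: (region, sector) × consuming region — the stressor-origin
    attribution of consumption; ``production``: per (region, sector);
    ``by_product``: final-product attribution, same shape as ``by_origin``.
    """

    metric: str
    component: str  # gas name, land-use type, or "total"
    index: pd.MultiIndex
    regions: list[str]
    production: pd.Series
    by_origin: pd.DataFrame
    by_product: pd.DataFrame

    @classmethod
    def compute(
        cls,
        metric: str,
        component: str,
        f: np.ndarray,
        system: MRIOSystem,
    ) -> "FootprintTensor":
        idx = system.index
        prod = pd.Series(production_footprints(f, system.x), index=idx, name="production")
        origin = pd.DataFrame(
            consumption_footprints(f, system.A, system.Y, by="origin"),
            index=idx,
            columns=system.regions,
        )
        product = pd.DataFrame(
            consumption_footprints(f, system.A, system.Y, by="product"),
            index=idx,
            columns=system.regions,
        )
        return cls(metric, component, idx, list(system.regions), prod, origin, product)

    # -- marginal views ---------------------------------------------------

    @property
    def production_by_region(self) -> pd.Series:
        return self.production.groupby(level="region", sort=False).sum()

    @property
    def consumption_by_region(self) -> pd.Series:
        return self.by_origin.sum(axis=0).rename_axis("region")

    @property
    def flows(self) -> pd.DataFrame:
        """Bilateral producing-region × consuming-region flow matrix."""
        return self.by_origin.groupby(level="region", sort=False).sum().loc[self.regions]

    def validate(self, rtol: float = 1e-8) -> None:
        """Marginal consistency: every view sums to the same global total."""
        total = float(self.production.sum())
        for other in (
            float(self.by_origin.values.sum()),
            float(self.by_product.values.sum()),
            float(self.flows.values.sum()),
        ):
            if not np.isclose(other, total, rtol=rtol, atol=1e-12 * max(1.0, abs(total))):
                raise ValueError(
                    f"inconsistent marginals for {self.metric}/{self.component}: "
                    f"{other!r} vs production total {total!r}"
                )
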