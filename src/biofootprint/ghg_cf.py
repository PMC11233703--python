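"""GHG-driven biodiversity characterization factors.

Emissions act on biodiversity globally, regardless of where they occur, via
warming.  The chain per €1M of a product p in region k:

1. ΔT_{p,k} = Σ_g E_{g,p,k} × C_g — the global mean warming at the 20-year
   horizon from the pulse of each gas, using absolute GTP coefficients
   (°C per kg, IPCC AR5 values by default).
2. F_x = ΔT_x / ΔT̄_x — a spatial weighting grid capturing that warming is
   not uniform; ΔT_x is the multi-model mean projected anomaly and ΔT̄_x its
   area-weighted mean over the weighting domain, so F̄ = 1 by construction.
3. ΔS_{x,p,k} = F_x × H_x × ΔT_{p,k} — fractional local richness change,
   with H_x the climate sensitivity (proportional change per °C, negative
   where warming costs species).
4. CF_{p,k} = −Σ_x ΔS_{x,p,k} × S_x × A_x — species × km² lost summed over
   the world, reported positive for loss.

Because ΔT_{p,k} is the only product-specific factor, the cell sum
factorises: CF_{p,k} = −ΔT_{p,k} × K with the kernel K = Σ_x F_x H_x S_x A_x.
Both routes are implemented and must agree; the kernel form makes explicit
that two regions with identical emission intensities receive identical CFs
no matter where they are or how rich their own territory is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mrio import ExtensionTable
from .world import WorldGrids

#: absolute global temperature change potentials at the 20-year horizon,
#: °C of global mean warming per kg of gas (IPCC AR5, Table 8.A.1)
AGTP_20YR = {"co2": 6.84e-16, "ch4": 4.62e-14, "n2o": 1.89e-13}


@dataclass(frozen=True)
class GTPConstants:
    """°C per kg per gas at the chosen horizon; defaults are the AR5 values."""

    C: dict[str, float] = field(default_factory=lambda: dict(AGTP_20YR))
    horizon_years: int = 20

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.C.values()):
            raise ValueError("GTP constants must be strictly positive")

    def __getitem__(self, gas: str) -> float:
        try:
            return self.C[gas]
        except KeyError:
            raise KeyError(f"no GTP constant for gas {gas!r}") from None


def warming_per_output(
    extensions: ExtensionTable, constants: GTPConstants | None = None
) -> pd.DataFrame:
    """ΔT_{p,k,g} and the gas-summed ΔT_{p,k}, °C per €1M of each product.

    Indexed like the emissions table ((region, sector)); one column per gas
    plus ``total``.  Raises on a gas with no GTP constant.
    """
    constants = constants or GTPConstants()
    emis = extensions.emissions
    out = pd.DataFrame(index=emis.index)
    for gas in emis.columns:
        out[gas] = emis[gas] * constants[gas]
    out["total"] = out.sum(axis=1)
    return out


@dataclass
class ClimateWeighting:
    """F_x grid and the global-mean anomaly it was normalised by."""

    F: np.ndarray
    mean_anomaly: float  # ΔT̄_x, °C
    domain: np.ndarray  # boolean mask of the weighting domain

    def validate(self, cell_area: float, tol: float = 1e-10) -> None:
        m = float(np.average(self.F[self.domain]))  # equal-area cells
        if abs(m - 1.0) > tol:
            raise ValueError(f"area-weighted mean of F_x is {m}, expected 1")


def temperature_weights(grids: WorldGrids, domain: str = "land") -> ClimateWeighting:
    """Multi-model mean anomaly normalised to the spatial weighting grid F_x.

    ``domain`` selects the cells over which the area-weighted global mean
    ΔT̄_x is taken: ``'land'`` (default) uses unmasked terrestrial cells,
    ``'all'`` the whole grid.  Equal cell areas make the area weighting a
    plain average.  A zero mean anomaly is degenerate and raises.
    """
    anomaly = grids.layer("anomaly").mean(axis=0)  # multi-model mean ΔT_x
    if domain == "land":
        mask = grids.land
    elif domain == "all":
        mask = np.ones_like(anomaly, dtype=bool)
    else:
        raise ValueError(f"unknown weighting domain {domain!r}")
    mean = float(np.average(anomaly[mask]))
    if mean == 0.0:
        raise ValueError("degenerate climate: global mean anomaly is zero")
    return ClimateWeighting(F=anomaly / mean, mean_anomaly=mean, domain=mask)


def biodiversity_kernel(
    weighting: ClimateWeighting, grids: WorldGrids, metric: str = "richness"
) -> float:
    """K = Σ_x F_x H_x S_x A_x over unmasked cells (species × km² per °C)."""
    mask = grids.unmasked
    H = grids.sensitivity_layer(metric)
    S = grids.metric_layer(metric)
    return float(np.sum(weighting.F[mask] * H[mask] * S[mask]) * grids.cell_area)


def ghg_characterization_factors(
    warming: pd.DataFrame,
    weighting: ClimateWeighting,
    grids: WorldGrids,
    metric: str = "richness",
    method: str = "kernel",
) -> pd.DataFrame:
    """CFs per (region, product, gas) for one metric, tidy long format.

    ``method='kernel'`` computes CF = −ΔT × K; ``method='cellwise'`` carries
    the full ΔS_{x,p,k} grid per product through the Eq. 7→8 sum.  The two
    must agree to machine precision; both are exposed so the equivalence is
    testable rather than assumed.
    """
    mask = grids.unmasked
    H = grids.sensitivity_layer(metric)
    S = grids.metric_layer(metric)
    gases = [c for c in warming.columns if c != "total"]
    K = biodiversity_kernel(weighting, grids, metric)

    rows = []
    for (region, sector), per_gas in warming.iterrows():
        for gas in gases + ["total"]:
            dT = float(per_gas[gas])
            if method == "kernel":
                cf = -dT * K
            elif method == "cellwise":
                dS_x = weighting.F * H * dT  # fractional change per cell
                cf = -float(np.sum(dS_x[mask] * S[mask]) * grids.cell_area)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(
                {
                    "region": region,
                    "product": sector,
                    "gas": gas,
                    "metric": metric,
                    "cf_value": cf,
                    "units": "species.km2_per_MEUR"
                    if metric == "richness"
                    else "rangefrac.km2_per_MEUR",
                }
            )
    return pd.DataFrame(rows)


def build_ghg_cfs(
    grids: WorldGrids,
    extensions: ExtensionTable,
    constants: GTPConstants | None = None,
    metrics: tuple[str, ...] = ("richness", "rarity"),
    domain: str = "land",
    method: str = "kernel",
) -> pd.DataFrame:
    """Full GHG-CF pipeline over metrics and gases."""
    warming = warming_per_output(extensions, constants)
    weighting = temperature_weights(grids, domain=domain)
    weighting.validate(grids.cell_area)
    return pd.concat(
        [
            ghg_characterization_factors(warming, weighting, grids, metric=m, method=method)
            for m in metrics
        ],
        ignore_index=True,
    )


def ghg_intensity_vector(
    cf_table: pd.DataFrame, index: pd.MultiIndex, metric: str, gas: str = "total"
) -> np.ndarray:
    """Map CF_{p,k,g} onto a direct-intensity vector over (region, sector)."""
    sub = cf_table[(cf_table["metric"] == metric) & (cf_table["gas"] == gas)]
    lookup = sub.set_index(["region", "product"])["cf_value"]
    return lookup.reindex(index).fillna(0.0).to_numpy()
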