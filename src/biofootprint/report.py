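"""Derived indicators: trade balances, normalised footprints, aggregations.

All indicator functions take the labelled outputs of the footprint engine
(bilateral flow matrices, production/consumption series) and return tidy
pandas objects.  Undefined ratios (zero denominators) are flagged with NaN
plus a boolean column rather than silently propagating infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mrio import FootprintTensor


@dataclass
class RegionAttributes:
    """Population and land area per region plus grouping maps."""

    population: pd.Series  # persons
    land_area: pd.Series  # km²
    world_region: dict[str, str] | None = None  # region → aggregate region
    product_group: dict[str, str] | None = None  # sector → food group

    def check(self, regions: list[str]) -> None:
        for r in regions:
            if r not in self.population.index or self.population[r] <= 0:
                raise ValueError(f"missing or non-positive population for region {r!r}")
            if r not in self.land_area.index or self.land_area[r] <= 0:
                raise ValueError(f"missing or non-positive land area for region {r!r}")


def net_imports(flows: pd.DataFrame) -> pd.Series:
    """Net imported footprint per region: consumption − production.

    Positive = the region's consumption displaces more impact abroad than
    its territory exports; the global sum is zero by construction.
    """
    consumption = flows.sum(axis=0)
    production = flows.sum(axis=1)
    return (consumption - production.reindex(consumption.index)).rename("net_import")


def percent_imported(flows: pd.DataFrame) -> pd.DataFrame:
    """Share of each region's consumption footprint occurring abroad, in %.

    100 × (consumption_r − domestic flow E_{r→r}) / consumption_r.  Regions
    with zero consumption get NaN and an ``undefined`` flag.
    """
    consumption = flows.sum(axis=0)
    domestic = pd.Series(np.diag(flows.values), index=flows.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (consumption - domestic) / consumption
    undefined = consumption == 0
    pct[undefined] = np.nan
    return pd.DataFrame({"pct_imported": pct, "undefined": undefined})


def normalize_footprints(
    production: pd.Series, consumption: pd.Series, attrs: RegionAttributes
) -> pd.DataFrame:
    """Per-km² production and per-capita consumption footprints.

    Production is normalised by territory (impacts sit on the land) and
    consumption by population (impacts follow demand).
    """
    regions = list(consumption.index)
    attrs.check(regions)
    return pd.DataFrame(
        {
            "per_area": production / attrs.land_area.reindex(production.index),
            "per_capita": consumption / attrs.population.reindex(consumption.index),
        }
    )


def land_ghg_ratio(land: pd.Series, ghg: pd.Series) -> pd.DataFrame:
    """Ratio of land-driven to GHG-driven loss, same metric basis.

    The ratio reads crudely as years-to-equal: at constant annual emissions,
    a ratio of 100 means a century of emissions matches the loss from all
    the land conversion behind one year's production.  Zero GHG footprints
    give NaN plus an ``undefined`` flag.
    """
    ghg = ghg.reindex(land.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = land / ghg
    undefined = ghg == 0
    ratio[undefined] = np.nan
    return pd.DataFrame(
        {"land_ghg_ratio": ratio, "undefined": undefined, "years_to_equal": ratio}
    )


def aggregate(values: pd.Series, grouping: dict[str, str], strict: bool = True) -> pd.Series:
    """Sum values into named groups; totals are preserved exactly.

    ``grouping`` maps member label → group label.  With ``strict`` an
    unmapped member raises; otherwise it keeps its own label.
    """
    def to_group(label: str) -> str:
        if label in grouping:
            return grouping[label]
        if strict:
            raise KeyError(f"no group mapping for {label!r}")
        return label

    groups = [to_group(lbl) for lbl in values.index]
    return values.groupby(pd.Index(groups, name="group")).sum()


#: default food-group map for the synthetic sector roster, mirroring the
#: coarse figure groupings (animal- vs plant-derived, other food, fertilizer)
DEFAULT_FOOD_GROUPS = {
    "crops": "plant_derived",
    "livestock": "animal_derived",
    "food_processing": "other_food",
    "fertilizer": "fertilizer",
}


def indicator_table(tensor: FootprintTensor, attrs: RegionAttributes | None = None) -> pd.DataFrame:
    """One-stop per-region indicator table for one footprint tensor."""
    flows = tensor.flows
    production = tensor.production_by_region
    consumption = tensor.consumption_by_region
    out = pd.DataFrame(
        {
            "production": production,
            "consumption": consumption,
            "net_import": net_imports(flows),
        }
    )
    out = out.join(percent_imported(flows))
    if attrs is not None:
        out = out.join(normalize_footprints(production, consumption, attrs))
    out.insert(0, "metric", tensor.metric)
    out.insert(1, "component", tensor.component)
    return out.rename_axis("region")
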