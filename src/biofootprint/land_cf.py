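"""Land-driven biodiversity characterization factors.

The land CF of a land-using sector converts €1M of its output into a
biodiversity loss in species × km² (or range-fraction × km² for the
rarity-weighted metric).  The chain is:

1. For each stratum (land-use type i, biome j, trade region k), the mean
   pristine richness S_{i,j,k} over the land the land-use actually occupies
   (weighted by land-use fraction × cell area).
2. ΔS_{i,j,k} = S_{i,j,k} × P_{j,l(i)}, where P is the proportional change
   in the metric under land-use class l relative to primary vegetation in
   biome j (negative = loss; P comes from survey-based models and is
   consumed here as an input table).
3. ΔS_{i,k} = Σ_j ΔS_{i,j,k} × B_{i,j,k}, the biome-share-weighted change,
   with B the proportion of land-use i's area in region k lying in biome j.
4. CF_{i,k} = −ΔS_{i,k} × A_{i,k}, with A_{i,k} the km² of land-use i needed
   per €1M of output.  The sign flip reports losses as positive; genuine
   gains (positive P) propagate as negative CFs.

Cells in excluded biomes drop out of every numerator and denominator, so
biome shares renormalise over the covered biomes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mrio import ExtensionTable
from .world import WorldGrids

#: default biome groupings used by the synthetic landscape, equator → pole
DEFAULT_BIOMES = [
    "tropical_forest",
    "tropical_grassland",
    "temperate_boreal_forest",
    "temperate_montane_grassland",
    "mediterranean",
    "drylands",
]

#: land-use classes of the survey-based sensitivity model
DEFAULT_CLASSES = ["cropland", "pasture", "secondary"]

#: default map: land-use type → sensitivity land-use class
DEFAULT_CORRESPONDENCE = {"cropland": "cropland", "pasture": "pasture"}


def default_sensitivity_table(biomes: list[str] | None = None) -> pd.DataFrame:
    """Synthetic P_{j,l} values: proportional metric change vs primary
    vegetation, by biome and land-use class.  Tropical biomes are the most
    sensitive; values are plausible magnitudes, not survey estimates."""
    biomes = biomes or DEFAULT_BIOMES
    base = {
        "tropical_forest": {"cropland": -0.45, "pasture": -0.35, "secondary": -0.20},
        "tropical_grassland": {"cropland": -0.35, "pasture": -0.20, "secondary": -0.12},
        "temperate_boreal_forest": {"cropland": -0.30, "pasture": -0.22, "secondary": -0.10},
        "temperate_montane_grassland": {"cropland": -0.25, "pasture": -0.12, "secondary": -0.08},
        "mediterranean": {"cropland": -0.30, "pasture": -0.18, "secondary": -0.10},
        "drylands": {"cropland": -0.20, "pasture": -0.10, "secondary": -0.05},
    }
    rows = {}
    for i, b in enumerate(biomes):
        rows[b] = base.get(b, {"cropland": -0.30 + 0.02 * i, "pasture": -0.15, "secondary": -0.08})
    return pd.DataFrame.from_dict(rows, orient="index")[DEFAULT_CLASSES].rename_axis("biome")


@dataclass
class SensitivityTable:
    """P_{j,l} land-use sensitivities plus the land-use-type correspondence.

    ``P``: DataFrame, rows = biome names, columns = land-use classes; each
    entry is the proportional change of the metric (> −1; −0.3 = 30% lower
    than primary vegetation).  ``correspondence`` maps every land-use type
    to its class.
    """

    P: pd.DataFrame = field(default_factory=default_sensitivity_table)
    correspondence: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CORRESPONDENCE))

    def __post_init__(self) -> None:
        if (self.P.values <= -1).any():
            raise ValueError("sensitivities must be > -1 (cannot lose more than all species)")

    def lookup(self, biome: str, landuse: str) -> float:
        cls = self.correspondence.get(landuse)
        if cls is None:
            raise KeyError(f"no land-use class correspondence for land-use type {landuse!r}")
        if biome not in self.P.index or cls not in self.P.columns:
            raise KeyError(f"no sensitivity value for (biome={biome!r}, class={cls!r})")
        return float(self.P.loc[biome, cls])

    @classmethod
    def from_csv(cls, path, correspondence: dict[str, str] | None = None) -> "SensitivityTable":
        p = pd.read_csv(path, index_col="biome")
        return cls(P=p, correspondence=correspondence or dict(DEFAULT_CORRESPONDENCE))


def _biome_names(grids: WorldGrids, biomes: list[str] | None) -> list[str]:
    n = int(grids.ds["biome_id"].values.max()) + 1
    names = biomes or DEFAULT_BIOMES
    if n > len(names):
        names = names + [f"biome_{i}" for i in range(len(names), n)]
    return names[: max(n, 1)]


def stratum_table(
    grids: WorldGrids,
    metric: str = "richness",
    regions: list[str] | None = None,
    biomes: list[str] | None = None,
    weighted: bool = True,
    min_area: float | None = None,
) -> pd.DataFrame:
    """Per-stratum area and mean pristine richness S_{i,j,k}.

    One row per populated (landuse, biome, region) stratum with columns
    ``area_km2`` (Σ fraction × cell area), ``S`` (the stratum mean of the
    metric layer, land-use-area weighted by default, plain cell mean when
    ``weighted=False``) and ``small`` flagging strata whose land-use area
    falls below ``min_area`` (default: one cell).  Strata with zero area are
    absent.  Masked cells never contribute.
    """
    layer = grids.metric_layer(metric)
    unmasked = grids.unmasked
    region_id = grids.layer("region_id")
    biome_id = grids.layer("biome_id")
    biome_names = _biome_names(grids, biomes)
    min_area = grids.cell_area if min_area is None else min_area

    rows = []
    for lu in grids.landuse_types():
        frac = grids.landuse_fraction(lu)
        area_w = frac * grids.cell_area
        use = unmasked & (frac > 0)
        if not use.any():
            continue
        df = pd.DataFrame(
            {
                "region_idx": region_id[use],
                "biome_idx": biome_id[use],
                "area": area_w[use],
                "value": layer[use],
            }
        )
        df["weight"] = df["area"] if weighted else 1.0
        g = df.groupby(["region_idx", "biome_idx"], sort=True)
        agg = pd.DataFrame(
            {
                "area_km2": g["area"].sum(),
                "S": g.apply(
                    lambda d: np.average(d["value"], weights=d["weight"]),
                    include_groups=False,
                ),
            }
        ).reset_index()
        agg.insert(0, "landuse", lu)
        rows.append(agg)
    if not rows:
        return pd.DataFrame(columns=["landuse", "biome", "region", "area_km2", "S", "small"])
    out = pd.concat(rows, ignore_index=True)
    n_regions = int(region_id[unmasked].max()) + 1 if unmasked.any() else 0
    region_names = regions or [f"R{i:02d}" for i in range(n_regions)]
    out["region"] = [region_names[i] for i in out["region_idx"]]
    out["biome"] = [biome_names[i] for i in out["biome_idx"]]
    out["small"] = out["area_km2"] < min_area
    return out[["landuse", "biome", "region", "area_km2", "S", "small"]]


def biome_shares(strata: pd.DataFrame) -> pd.DataFrame:
    """Attach B_{i,j,k}: share of the (landuse, region) area lying in each biome.

    Sums to 1 over the covered biomes of every populated (landuse, region);
    zero-area strata are already absent from the table so no NaNs arise.
    """
    out = strata.copy()
    totals = out.groupby(["landuse", "region"])["area_km2"].transform("sum")
    out["B"] = out["area_km2"] / totals
    return out


def land_delta_richness(strata: pd.DataFrame, sensitivity: SensitivityTable) -> pd.DataFrame:
    """ΔS per stratum and the biome-share-weighted ΔS_{i,k} per (landuse, region).

    Returns a DataFrame indexed (landuse, region) with column ``dS``
    (negative = loss) plus the per-stratum table with ``dS_stratum``.
    Raises KeyError naming the pair when a populated stratum has no
    sensitivity entry.
    """
    if "B" not in strata.columns:
        strata = biome_shares(strata)
    out = strata.copy()
    out["dS_stratum"] = [
        row.S * sensitivity.lookup(row.biome, row.landuse) for row in out.itertuples()
    ]
    dS = (
        (out["dS_stratum"] * out["B"])
        .groupby([out["landuse"], out["region"]])
        .sum()
        .rename("dS")
        .reset_index()
    )
    return dS, out


def land_characterization_factors(
    dS: pd.DataFrame,
    extensions: ExtensionTable,
    metric: str = "richness",
) -> pd.DataFrame:
    """Eq.-4 step: CF_{i,k} = −ΔS_{i,k} × A_{i,k}, tidy long format.

    A_{i,k} is the km² of land-use type i per €1M of output summed over the
    sectors that use it in region k (in the synthetic economy exactly one
    sector carries each land-use type).  Reported positive for losses.
    """
    if (extensions.land_area.values < 0).any():
        raise ValueError("negative land-area intensity")
    intens = (
        extensions.land_area.groupby(level="region")
        .sum()
        .rename_axis(index="region")
    )
    rows = []
    for row in dS.itertuples():
        a = float(intens.loc[row.region, row.landuse]) if row.landuse in intens.columns else 0.0
        rows.append(
            {
                "landuse": row.landuse,
                "region": row.region,
                "metric": metric,
                "cf_value": -row.dS * a,
                "units": "species.km2_per_MEUR" if metric == "richness" else "rangefrac.km2_per_MEUR",
            }
        )
    return pd.DataFrame(rows)


def build_land_cfs(
    grids: WorldGrids,
    extensions: ExtensionTable,
    sensitivity: SensitivityTable,
    regions: list[str] | None = None,
    metrics: tuple[str, ...] = ("richness", "rarity"),
    weighted: bool = True,
) -> pd.DataFrame:
    """Full land-CF pipeline for one or more biodiversity metrics."""
    tables = []
    for metric in metrics:
        strata = stratum_table(grids, metric=metric, regions=regions, weighted=weighted)
        strata = biome_shares(strata)
        dS, _ = land_delta_richness(strata, sensitivity)
        tables.append(land_characterization_factors(dS, extensions, metric=metric))
    return pd.concat(tables, ignore_index=True)


def land_intensity_vector(
    cf_table: pd.DataFrame,
    extensions: ExtensionTable,
    index: pd.MultiIndex,
    metric: str,
) -> np.ndarray:
    """Map CF_{i,k} onto a direct-intensity vector over (region, sector).

    A sector's intensity is Σ_i CF_{i,k} × (its share of region k's land-use
    i intensity), which for the one-sector-per-land-use economy places
    CF_{i,k} on the sector carrying land-use i and zero elsewhere.
    """
    sub = cf_table[cf_table["metric"] == metric]
    region_tot = extensions.land_area.groupby(level="region").sum()
    f = np.zeros(len(index))
    for pos, (region, sector) in enumerate(index):
        la = extensions.land_area.loc[(region, sector)]
        val = 0.0
        for row in sub[sub["region"] == region].itertuples():
            tot = float(region_tot.loc[region, row.landuse])
            if tot > 0 and row.landuse in la.index and la[row.landuse] > 0:
                val += row.cf_value * (la[row.landuse] / tot)
        f[pos] = val
    return f


def land_area_intensity_vector(extensions: ExtensionTable, index: pd.MultiIndex) -> np.ndarray:
    """Plain land-area direct intensity (km² per €1M), all land-use types."""
    return extensions.land_area.reindex(index).fillna(0.0).sum(axis=1).to_numpy()
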