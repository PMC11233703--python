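"""Land CF chain: hand-computed strata, biome shares, cell-level oracle."""

import numpy as np
import pandas as pd
import pytest

from biofootprint import SensitivityTable, build_land_cfs, generate_world
from biofootprint.land_cf import (
    biome_shares,
    land_characterization_factors,
    land_delta_richness,
    stratum_table,
)
from biofootprint.synth import WorldConfig
from conftest import make_extensions, make_grids


from biofootprint.land_cf import DEFAULT_BIOMES


def flat_sensitivity(value, biomes=tuple(DEFAULT_BIOMES), classes=("cropland", "pasture")):
    P = pd.DataFrame(value, index=list(biomes), columns=list(classes)).rename_axis("biome")
    corr = {c: c for c in classes}
    return SensitivityTable(P=P, correspondence=corr)


def brute_force_land_cf(grids, extensions, sensitivity, regions, metric="richness"):
    """Independent cell-level oracle: per (landuse, region),
    ΔS = Σ_x frac·area·S·P(biome(x)) / Σ_x frac·area, then CF = −ΔS·A."""
    layer = grids.metric_layer(metric)
    region_id, biome_id = grids.layer("region_id"), grids.layer("biome_id")
    unmasked = grids.unmasked
    biome_names = _oracle_biome_names(grids)
    intens = extensions.land_area.groupby(level="region").sum()
    out = {}
    for lu in grids.landuse_types():
        frac = grids.landuse_fraction(lu)
        for k, region in enumerate(regions):
            num = den = 0.0
            for y in range(grids.shape[0]):
                for x in range(grids.shape[1]):
                    if not unmasked[y, x] or region_id[y, x] != k or frac[y, x] <= 0:
                        continue
                    w = frac[y, x] * grids.cell_area
                    p = sensitivity.lookup(biome_names[biome_id[y, x]], lu)
                    num += w * layer[y, x] * p
                    den += w
            if den > 0:
                out[(lu, region)] = -(num / den) * float(intens.loc[region, lu])
    return out


def _oracle_biome_names(grids):
    from biofootprint.land_cf import _biome_names

    return _biome_names(grids, None)


class TestStratumMeanRichness:
    def test_constant_richness_gives_constant_stratum_means(self):
        grids = make_grids([[0, 0], [0, 0]], [[0, 0], [1, 1]],
                           {"cropland": [[0.5, 0.5], [0.2, 0.2]]},
                           richness=[[50.0, 50.0], [50.0, 50.0]])
        strata = stratum_table(grids, regions=["R0"])
        assert (strata["S"] == 50.0).all()

    def test_area_weighted_mean_hand_example(self):
        """Richness 10 and 20 with land areas 1:3 → weighted mean 17.5."""
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.1, 0.3]]},
                           richness=[[10.0, 20.0]], cell_area=10.0)
        strata = stratum_table(grids, regions=["R0"])
        assert strata["S"].iloc[0] == pytest.approx(17.5)

    def test_unweighted_switch_gives_plain_cell_mean(self):
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.1, 0.3]]},
                           richness=[[10.0, 20.0]], cell_area=10.0)
        strata = stratum_table(grids, regions=["R0"], weighted=False)
        assert strata["S"].iloc[0] == pytest.approx(15.0)

    def test_zero_fraction_cells_contribute_nothing(self):
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.4, 0.0]]},
                           richness=[[10.0, 999.0]])
        strata = stratum_table(grids, regions=["R0"])
        assert strata["S"].iloc[0] == pytest.approx(10.0)

    def test_small_strata_flagged_not_dropped(self):
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.01, 0.0]]},
                           richness=[[10.0, 10.0]], cell_area=100.0)
        strata = stratum_table(grids, regions=["R0"])
        assert len(strata) == 1 and bool(strata["small"].iloc[0])

    def test_excluded_biome_cells_never_counted(self):
        grids = make_grids([[0, 0]], [[0, -1]], {"cropland": [[0.5, 0.5]]},
                           richness=[[10.0, 1000.0]])
        strata = stratum_table(grids, regions=["R0"])
        assert strata["S"].iloc[0] == pytest.approx(10.0)


class TestBiomeShares:
    def test_single_biome_share_is_one(self):
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.5, 0.5]]},
                           richness=[[1.0, 1.0]])
        strata = biome_shares(stratum_table(grids, regions=["R0"]))
        assert strata["B"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_shares(self):
        """30 km² in biome 0 and 10 km² in biome 1 → shares 0.75 / 0.25."""
        grids = make_grids([[0, 0]], [[0, 1]], {"cropland": [[0.3, 0.1]]},
                           richness=[[1.0, 1.0]], cell_area=100.0)
        strata = biome_shares(stratum_table(grids, regions=["R0"]))
        shares = strata.set_index("biome")["B"]
        assert shares.iloc[0] == pytest.approx(0.75)
        assert shares.iloc[1] == pytest.approx(0.25)

    def test_shares_sum_to_one_on_synthetic_world(self, small_world):
        strata = biome_shares(stratum_table(small_world.grids,
                                            regions=small_world.system.regions))
        sums = strata.groupby(["landuse", "region"])["B"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-10)


class TestDeltaRichness:
    def test_zero_sensitivity_nulls_all_deltas(self):
        grids = make_grids([[0, 0]], [[0, 1]], {"cropland": [[0.3, 0.1]]},
                           richness=[[10.0, 20.0]])
        dS, _ = land_delta_richness(stratum_table(grids, regions=["R0"]),
                                    flat_sensitivity(0.0))
        assert (dS["dS"] == 0.0).all()

    def test_stratum_delta_is_direct_product(self):
        """S = 100, P = −0.3 → ΔS stratum = −30."""
        grids = make_grids([[0]], [[0]], {"cropland": [[0.5]]}, richness=[[100.0]])
        _, strata = land_delta_richness(stratum_table(grids, regions=["R0"]),
                                        flat_sensitivity(-0.3))
        assert strata["dS_stratum"].iloc[0] == pytest.approx(-30.0)

    def test_biome_share_weighted_sum(self):
        """ΔS strata (−30, −10) with shares (0.75, 0.25) → ΔS = −25."""
        sens = SensitivityTable(
            P=pd.DataFrame({"cropland": [-0.3, -0.1]},
                           index=DEFAULT_BIOMES[:2]).rename_axis("biome"),
            correspondence={"cropland": "cropland"},
        )
        grids = make_grids([[0, 0]], [[0, 1]], {"cropland": [[0.3, 0.1]]},
                           richness=[[100.0, 100.0]], cell_area=100.0)
        dS, _ = land_delta_richness(stratum_table(grids, regions=["R0"]), sens)
        assert dS["dS"].iloc[0] == pytest.approx(-25.0)

    def test_missing_sensitivity_entry_names_the_pair(self):
        grids = make_grids([[0]], [[0]], {"orchard": [[0.5]]}, richness=[[1.0]])
        with pytest.raises(KeyError, match="orchard"):
            land_delta_richness(stratum_table(grids, regions=["R0"]),
                                flat_sensitivity(-0.1))


class TestCharacterizationFactors:
    def test_hand_product(self):
        """ΔS = −25 species, A = 2 km²/€1M → CF = +50 species·km² per €1M."""
        dS = pd.DataFrame({"landuse": ["cropland"], "region": ["R0"], "dS": [-25.0]})
        ext = make_extensions(pd.MultiIndex.from_tuples([("R0", "crops")],
                                                        names=["region", "sector"]),
                              land=2.0)
        cf = land_characterization_factors(dS, ext)
        assert cf["cf_value"].iloc[0] == pytest.approx(50.0)

    def test_zero_land_intensity_zero_cf(self):
        dS = pd.DataFrame({"landuse": ["cropland"], "region": ["R0"], "dS": [-25.0]})
        ext = make_extensions(pd.MultiIndex.from_tuples([("R0", "crops")],
                                                        names=["region", "sector"]))
        assert land_characterization_factors(dS, ext)["cf_value"].iloc[0] == 0.0

    def test_gains_propagate_as_negative_cfs(self):
        dS = pd.DataFrame({"landuse": ["cropland"], "region": ["R0"], "dS": [5.0]})
        ext = make_extensions(pd.MultiIndex.from_tuples([("R0", "crops")],
                                                        names=["region", "sector"]),
                              land=2.0)
        assert land_characterization_factors(dS, ext)["cf_value"].iloc[0] == -10.0


class TestPipelineProperties:
    def test_matches_cell_level_brute_force(self):
        """Stratified pipeline ≡ independent cell-level loop, 30×30 world."""
        world = generate_world(WorldConfig(seed=21, ny=30, nx=30, n_regions=3,
                                           n_species=120))
        sens = SensitivityTable()
        cfs = build_land_cfs(world.grids, world.extensions, sens,
                             regions=world.system.regions, metrics=("richness",))
        oracle = brute_force_land_cf(world.grids, world.extensions, sens,
                                     world.system.regions)
        table = cfs.set_index(["landuse", "region"])["cf_value"]
        assert set(oracle) == set(table.index)
        for key, expected in oracle.items():
            assert table[key] == pytest.approx(expected, rel=1e-8)

    def test_homogeneity_in_richness_layer(self, small_world):
        sens = SensitivityTable()
        base = build_land_cfs(small_world.grids, small_world.extensions, sens,
                              regions=small_world.system.regions, metrics=("richness",))
        scaled_grids = small_world.grids
        scaled_grids.ds["richness"] = scaled_grids.ds["richness"] * 3.0
        try:
            scaled = build_land_cfs(scaled_grids, small_world.extensions, sens,
                                    regions=small_world.system.regions,
                                    metrics=("richness",))
        finally:
            scaled_grids.ds["richness"] = scaled_grids.ds["richness"] / 3.0
        np.testing.assert_allclose(scaled["cf_value"], 3.0 * base["cf_value"], rtol=1e-12)

    def test_metric_pipelines_identical_when_layers_identical(self, small_world):
        grids = small_world.grids
        saved = grids.ds["rarity"].copy()
        grids.ds["rarity"] = grids.ds["richness"]
        try:
            cfs = build_land_cfs(grids, small_world.extensions, SensitivityTable(),
                                 regions=small_world.system.regions)
        finally:
            grids.ds["rarity"] = saved
        rich = cfs[cfs["metric"] == "richness"].set_index(["landuse", "region"])["cf_value"]
        rare = cfs[cfs["metric"] == "rarity"].set_index(["landuse", "region"])["cf_value"]
        np.testing.assert_allclose(rich.to_numpy(), rare.reindex(rich.index).to_numpy(),
                                   rtol=1e-14)
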