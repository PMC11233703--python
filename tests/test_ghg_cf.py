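"""GHG CF chain: GTP worked examples, weighting grid, kernel duality."""

import numpy as np
import pandas as pd
import pytest

from biofootprint import GTPConstants, build_ghg_cfs, warming_per_output
from biofootprint.ghg_cf import (
    biodiversity_kernel,
    ghg_characterization_factors,
    temperature_weights,
)
from conftest import make_extensions, make_grids


def one_region_index(sector="crops"):
    return pd.MultiIndex.from_tuples([("R0", sector)], names=["region", "sector"])


class TestWarmingPerOutput:
    @pytest.mark.parametrize(
        "gas,coef",
        [("co2", 6.84e-16), ("ch4", 4.62e-14), ("n2o", 1.89e-13)],
    )
    def test_unit_pulse_recovers_gtp_coefficient(self, gas, coef):
        """1 kg of a single gas warms by exactly its 20-yr GTP coefficient."""
        emis = {"co2": 0.0, "ch4": 0.0, "n2o": 0.0}
        emis[gas] = 1.0
        ext = make_extensions(one_region_index(),
                              emissions=[list(emis.values())])
        warming = warming_per_output(ext)
        assert warming["total"].iloc[0] == coef

    def test_zero_emissions_zero_warming(self):
        ext = make_extensions(one_region_index())
        assert warming_per_output(ext)["total"].iloc[0] == 0.0

    def test_mixed_pulse_matches_scalar_dot_product(self):
        """E = (1e9, 1e6, 0) kg → ΔT = 7.302e-7 °C by independent dot product."""
        ext = make_extensions(one_region_index(), emissions=[[1e9, 1e6, 0.0]])
        warming = warming_per_output(ext)
        expected = 1e9 * 6.84e-16 + 1e6 * 4.62e-14 + 0.0 * 1.89e-13
        assert expected == pytest.approx(7.302e-7, rel=1e-12)
        assert warming["total"].iloc[0] == pytest.approx(expected, rel=1e-14)

    def test_unknown_gas_rejected(self):
        ext = make_extensions(one_region_index(), gases=("co2", "sf6"),
                              emissions=[[1.0, 1.0]])
        with pytest.raises(KeyError, match="sf6"):
            warming_per_output(ext)

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            GTPConstants(C={"co2": 0.0})


class TestTemperatureWeights:
    def test_uniform_anomaly_unit_weights(self):
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.1, 0.1]]},
                           richness=[[1.0, 1.0]], anomaly=[[[0.5, 0.5]]])
        w = temperature_weights(grids)
        np.testing.assert_allclose(w.F, 1.0)

    def test_two_cell_hand_example(self):
        """Anomalies 1 °C and 3 °C on equal areas → F = (0.5, 1.5)."""
        grids = make_grids([[0, 0]], [[0, 0]], {"cropland": [[0.1, 0.1]]},
                           richness=[[1.0, 1.0]], anomaly=[[[1.0, 3.0]]])
        w = temperature_weights(grids)
        np.testing.assert_allclose(w.F, [[0.5, 1.5]])
        assert w.mean_anomaly == pytest.approx(2.0)

    def test_area_weighted_mean_is_one_on_random_field(self):
        rng = np.random.default_rng(17)
        anom = 0.5 + 0.2 * rng.random((2, 40, 40))
        grids = make_grids(np.zeros((40, 40)), np.zeros((40, 40)),
                           {"cropland": np.full((40, 40), 0.2)},
                           richness=np.ones((40, 40)), anomaly=anom)
        w = temperature_weights(grids)
        # independent weighted-mean oracle (equal areas → plain mean)
        assert abs(np.mean(w.F[w.domain]) - 1.0) < 1e-10

    def test_degenerate_zero_anomaly_raises(self):
        grids = make_grids([[0]], [[0]], {"cropland": [[0.1]]},
                           richness=[[1.0]], anomaly=[[[0.0]]])
        with pytest.raises(ValueError, match="degenerate"):
            temperature_weights(grids)


class TestGhgCharacterizationFactors:
    def single_cell_setup(self, H=-0.01, S=100.0, cell_area=10.0):
        grids = make_grids([[0]], [[0]], {"cropland": [[0.5]]},
                           richness=[[S]], anomaly=[[[1.0]]],
                           sensitivity={"richness": [[H]]}, cell_area=cell_area)
        return grids

    def test_single_cell_hand_computation(self):
        """F=1, H=−0.01/°C, S=100, A=10 km², ΔT=1e-6 °C → CF = 1e-5 loss."""
        grids = self.single_cell_setup()
        w = temperature_weights(grids)
        warming = pd.DataFrame({"total": [1e-6]}, index=one_region_index())
        cf = ghg_characterization_factors(warming, w, grids)
        total = cf[cf["gas"] == "total"]["cf_value"].iloc[0]
        assert total == pytest.approx(1e-5, rel=1e-12)

    def test_zero_sensitivity_zero_cf(self):
        grids = self.single_cell_setup(H=0.0)
        w = temperature_weights(grids)
        warming = pd.DataFrame({"total": [1e-6]}, index=one_region_index())
        cf = ghg_characterization_factors(warming, w, grids)
        assert (cf["cf_value"] == 0.0).all()

    def test_doubling_emissions_doubles_cf(self, small_world):
        base = build_ghg_cfs(small_world.grids, small_world.extensions,
                             metrics=("richness",))
        doubled_ext = make_extensions(small_world.extensions.emissions.index,
                                      landuse_types=small_world.extensions.landuse_types,
                                      emissions=2.0 * small_world.extensions.emissions.values)
        doubled = build_ghg_cfs(small_world.grids, doubled_ext, metrics=("richness",))
        np.testing.assert_allclose(doubled["cf_value"], 2.0 * base["cf_value"], rtol=1e-14)

    def test_cellwise_equals_kernel_factorization(self, small_world):
        """Dual implementation pins the summed-over-cells reading."""
        for metric in ("richness", "rarity"):
            kern = build_ghg_cfs(small_world.grids, small_world.extensions,
                                 metrics=(metric,), method="kernel")
            cell = build_ghg_cfs(small_world.grids, small_world.extensions,
                                 metrics=(metric,), method="cellwise")
            np.testing.assert_allclose(kern["cf_value"], cell["cf_value"], rtol=1e-12)

    def test_gas_additivity(self, small_world):
        cfs = build_ghg_cfs(small_world.grids, small_world.extensions,
                            metrics=("richness",))
        wide = cfs.pivot_table(index=["region", "product"], columns="gas",
                               values="cf_value")
        np.testing.assert_allclose(wide["total"],
                                   wide[["co2", "ch4", "n2o"]].sum(axis=1), rtol=1e-12)

    def test_identical_emitters_get_identical_cfs_regardless_of_location(self):
        """Emissions act globally: two regions with the same intensities share CFs."""
        idx = pd.MultiIndex.from_tuples([("R0", "crops"), ("R1", "crops")],
                                        names=["region", "sector"])
        ext = make_extensions(idx, emissions=[[1e5, 1e3, 1e2], [1e5, 1e3, 1e2]])
        rng = np.random.default_rng(23)
        richness = rng.uniform(0, 50, (8, 8))
        richness[:4] *= 10  # region 0's own territory is far richer
        grids = make_grids(np.repeat([[0], [1]], [4, 4], axis=0) * np.ones((1, 8), int),
                           np.zeros((8, 8)), {"cropland": np.full((8, 8), 0.2)},
                           richness=richness, anomaly=[0.4 + 0.1 * rng.random((8, 8))],
                           sensitivity={"richness": np.full((8, 8), -0.01)})
        cfs = build_ghg_cfs(grids, ext, metrics=("richness",))
        total = cfs[cfs["gas"] == "total"].set_index("region")["cf_value"]
        assert total["R0"] == pytest.approx(total["R1"], rel=1e-14)

    def test_rarity_cfs_scale_with_proportional_layer(self, small_world):
        """rarity = c × richness and shared H_x ⇒ rarity CFs = c × richness CFs."""
        grids = small_world.grids
        saved = grids.ds["rarity"].copy()
        grids.ds["rarity"] = 0.01 * grids.ds["richness"]
        saved_sens = grids.ds["sensitivity"].copy()
        grids.ds["sensitivity"] = grids.ds["sensitivity"] * 0 + \
            grids.ds["sensitivity"].sel(metric="richness")
        try:
            cfs = build_ghg_cfs(grids, small_world.extensions)
        finally:
            grids.ds["rarity"] = saved
            grids.ds["sensitivity"] = saved_sens
        rich = cfs[(cfs["metric"] == "richness") & (cfs["gas"] == "total")]
        rare = cfs[(cfs["metric"] == "rarity") & (cfs["gas"] == "total")]
        np.testing.assert_allclose(rare["cf_value"].to_numpy(),
                                   0.01 * rich["cf_value"].to_numpy(), rtol=1e-12)

    def test_missing_metric_layer_is_an_error(self):
        grids = self.single_cell_setup()
        w = temperature_weights(grids)
        with pytest.raises(KeyError):
            biodiversity_kernel(w, grids, metric="rarity")
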