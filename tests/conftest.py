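import numpy as np
import pandas as pd
import pytest

from biofootprint import (
    ExtensionTable,
    GridSpec,
    MRIOSystem,
    PipelineConfig,
    SectorSpec,
    WorldConfig,
    generate_world,
    run_pipeline,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    cfg = WorldConfig(seed=7, ny=20, nx=20, n_regions=3, n_species=80)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def pipeline_result():
    """One default-sized pipeline run shared by read-only tests."""
    cfg = PipelineConfig(world=WorldConfig(seed=11, ny=24, nx=24, n_regions=3, n_species=150))
    return run_pipeline(cfg)


def make_system(A, Y, regions, sectors=None):
    """Hand-build a labelled MRIO system for structural tests."""
    n_sec = A.shape[0] // len(regions)
    if sectors is None:
        sectors = [SectorSpec(f"s{i}", food=True, landuse="cropland" if i == 0 else None)
                   for i in range(n_sec)]
    return MRIOSystem(regions=list(regions), sectors=sectors,
                      A=np.asarray(A, dtype=float), Y=np.asarray(Y, dtype=float))


def make_extensions(index, landuse_types=("cropland",), gases=("co2", "ch4", "n2o"),
                    land=None, emissions=None):
    la = pd.DataFrame(0.0, index=index, columns=list(landuse_types))
    em = pd.DataFrame(0.0, index=index, columns=list(gases))
    if land is not None:
        la.loc[:, :] = land
    if emissions is not None:
        em.loc[:, :] = emissions
    return ExtensionTable(land_area=la, emissions=em)


def make_grids(region_id, biome_id, fractions, richness=None, rarity=None,
               cell_area=1.0, anomaly=None, sensitivity=None):
    """Hand-build a WorldGrids from plain arrays.

    ``fractions``: dict land-use name → 2-D fraction array;
    ``anomaly``: (model, y, x) array; ``sensitivity``: dict metric → array.
    """
    import xarray as xr

    from biofootprint.world import WorldGrids

    region_id = np.asarray(region_id, dtype=np.int32)
    data = {
        "region_id": (("y", "x"), region_id),
        "biome_id": (("y", "x"), np.asarray(biome_id, dtype=np.int32)),
        "landuse_fraction": (
            ("landuse", "y", "x"),
            np.stack([np.asarray(v, dtype=float) for v in fractions.values()]),
        ),
    }
    coords = {"landuse": list(fractions)}
    if richness is not None:
        data["richness"] = (("y", "x"), np.asarray(richness, dtype=float))
    if rarity is not None:
        data["rarity"] = (("y", "x"), np.asarray(rarity, dtype=float))
    if anomaly is not None:
        anomaly = np.asarray(anomaly, dtype=float)
        data["anomaly"] = (("model", "y", "x"), anomaly)
        coords["model"] = [f"m{i}" for i in range(anomaly.shape[0])]
    if sensitivity is not None:
        data["sensitivity"] = (
            ("metric", "y", "x"),
            np.stack([np.asarray(v, dtype=float) for v in sensitivity.values()]),
        )
        coords["metric"] = list(sensitivity)
    ds = xr.Dataset(data, coords=coords, attrs={"cell_area": cell_area})
    return WorldGrids(ds, cell_area)


@pytest.fixture
def grid10():
    return GridSpec(10, 10, cell_area=4.0)
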