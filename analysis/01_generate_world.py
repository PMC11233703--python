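"""Generate the default synthetic world and write it under results/world/.

The world is a miniature, fully self-consistent stand-in for the study's
real inputs: a 4-region, 5-sector trading economy with land and emission
extensions, a 30×30 equal-area grid (100 km² cells) carrying 300 stacked
species ranges, biomes, land-use fractions, and a 4-model warming field.
"""

from pathlib import Path

from biofootprint import WorldConfig, generate_world
from biofootprint import io

OUT = Path(__file__).resolve().parent.parent / "results" / "world"
SEED = 2011  # the study year, reused as the default master seed


def main() -> None:
    cfg = WorldConfig(seed=SEED)
    world = generate_world(cfg)
    io.save_mrio(world.system, world.extensions, OUT / "economy")
    world.grids.to_netcdf(OUT / "grids.nc")

    richness = world.grids.layer("richness")
    print(f"world written to {OUT}")
    print(f"  regions: {world.system.regions}")
    print(f"  sectors: {world.system.sector_names}")
    print(f"  gross output total: {world.system.x.sum():,.0f} M EUR")
    print(f"  species richness: min {richness.min():.0f}, max {richness.max():.0f} per cell")
    print(f"  masked cells: {(~world.grids.unmasked).sum()} of {world.grids.n_cells}")


if __name__ == "__main__":
    main()
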