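"""Reading and writing the on-disk bundle: labelled CSV tables + NetCDF grids.

The MRIO dialect is labelled CSV with a region-major, sector-minor header
ordering: rows and columns of ``A.csv`` are ``region|sector`` composites,
columns of ``Y.csv`` are consuming regions.  Grids travel as NetCDF
(classic format); the manifest is YAML recording config and seed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .mrio import ExtensionTable, MRIOSystem, SectorSpec

SEP = "|"


def _flat(index: pd.MultiIndex) -> list[str]:
    return [f"{r}{SEP}{s}" for r, s in index]


def save_mrio(system: MRIOSystem, extensions: ExtensionTable, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = _flat(system.index)
    pd.DataFrame(system.A, index=labels, columns=labels).to_csv(outdir / "A.csv")
    pd.DataFrame(system.Y, index=labels, columns=system.regions).to_csv(outdir / "Y.csv")
    pd.Series(system.x, index=labels, name="gross_output").to_csv(outdir / "x.csv")
    pd.DataFrame(
        {
            "sector": [s.name for s in system.sectors],
            "food": [s.food for s in system.sectors],
            "landuse": [s.landuse or "" for s in system.sectors],
        }
    ).to_csv(outdir / "sectors.csv", index=False)
    ext_land = extensions.land_area.copy()
    ext_land.index = _flat(ext_land.index)
    ext_land.to_csv(outdir / "extensions_land.csv")
    ext_emis = extensions.emissions.copy()
    ext_emis.index = _flat(ext_emis.index)
    ext_emis.to_csv(outdir / "extensions_emissions.csv")


def load_mrio(indir: Path) -> tuple[MRIOSystem, ExtensionTable]:
    indir = Path(indir)
    A = pd.read_csv(indir / "A.csv", index_col=0)
    Y = pd.read_csv(indir / "Y.csv", index_col=0)
    sec = pd.read_csv(indir / "sectors.csv", keep_default_na=False)
    sectors = [
        SectorSpec(r.sector, food=bool(r.food), landuse=(r.landuse or None))
        for r in sec.itertuples()
    ]
    regions = list(Y.columns)
    system = MRIOSystem(regions=regions, sectors=sectors, A=A.to_numpy(), Y=Y.to_numpy())
    idx = system.index
    land = pd.read_csv(indir / "extensions_land.csv", index_col=0)
    emis = pd.read_csv(indir / "extensions_emissions.csv", index_col=0)
    land.index = idx
    emis.index = idx
    return system, ExtensionTable(land_area=land, emissions=emis)


def save_manifest(config_dict: dict, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict, sort_keys=True))


def load_manifest(path: Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
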