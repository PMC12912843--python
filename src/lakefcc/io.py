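"""File I/O: NetCDF scene/composite round-trips, TIFF layers, CSV tables.

Scenes and monthly composites travel as NetCDF (classic format via the
scipy backend, one file per date or month, variables chl/sst/par/kd490 plus
quality layers with units attributes); single layers can be exported as
plain single-band TIFF on the local metric grid. Tabular artefacts
(surveys, matchups, assessments) are CSV with the documented headers.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .qc import LakeMask, MatchupPair, MonthlyComposite
from .scenes import GridScene

__all__ = [
    "scene_to_dataset",
    "dataset_to_scene",
    "write_scene",
    "read_scene",
    "write_scenes",
    "read_scenes",
    "composite_to_dataset",
    "write_composite",
    "read_composite",
    "read_composites",
    "write_layer_tiff",
    "read_layer_tiff",
    "write_matchups_csv",
    "read_matchups_csv",
    "write_json",
]

_UNITS = {
    "chl": "mg m-3",
    "sst": "degC",
    "par": "mol quanta m-2 day-1",
    "kd490": "m-1",
    "flags": "1",
    "straylight_pct": "percent",
    "ice": "1",
    "water": "1",
}


def scene_to_dataset(scene: GridScene) -> xr.Dataset:
    data = {}
    for name in _UNITS:
        arr = getattr(scene, name)
        if arr.dtype == bool:
            arr = arr.astype("i1")
        data[name] = xr.DataArray(arr, dims=("row", "col"), attrs={"units": _UNITS[name]})
    return xr.Dataset(data, attrs={"date": scene.date.isoformat()})


def dataset_to_scene(ds: xr.Dataset) -> GridScene:
    return GridScene(
        date=datetime.date.fromisoformat(str(ds.attrs["date"])),
        chl=ds["chl"].values.astype(float),
        sst=ds["sst"].values.astype(float),
        par=ds["par"].values.astype(float),
        kd490=ds["kd490"].values.astype(float),
        flags=ds["flags"].values.astype(int),
        straylight_pct=ds["straylight_pct"].values.astype(float),
        ice=ds["ice"].values.astype(int),
        water=ds["water"].values.astype(bool),
    )


def write_scene(scene: GridScene, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scene_to_dataset(scene).to_netcdf(path, engine="scipy")
    return path


def read_scene(path: Path | str) -> GridScene:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_scene(ds.load())


def write_scenes(scenes: Sequence[GridScene], out_dir: Path | str) -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_scene(s, out_dir / f"scene_{s.date.isoformat()}.nc") for s in scenes]


def read_scenes(in_dir: Path | str) -> List[GridScene]:
    paths = sorted(Path(in_dir).glob("scene_*.nc"))
    if not paths:
        raise FileNotFoundError(f"no scene_*.nc files under {in_dir}")
    return [read_scene(p) for p in paths]


def composite_to_dataset(comp: MonthlyComposite) -> xr.Dataset:
    data = {
        name: xr.DataArray(getattr(comp, name), dims=("row", "col"),
                           attrs={"units": _UNITS[name]})
        for name in ("chl", "sst", "par", "kd490")
    }
    data["valid_days"] = xr.DataArray(comp.valid_days.astype("i4"), dims=("row", "col"))
    data["filled"] = xr.DataArray(comp.filled.astype("i1"), dims=("row", "col"))
    return xr.Dataset(data, attrs={"year": comp.year, "month": comp.month})


def write_composite(comp: MonthlyComposite, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    composite_to_dataset(comp).to_netcdf(path, engine="scipy")
    return path


def read_composite(path: Path | str) -> MonthlyComposite:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
        return MonthlyComposite(
            year=int(ds.attrs["year"]),
            month=int(ds.attrs["month"]),
            chl=ds["chl"].values.astype(float),
            sst=ds["sst"].values.astype(float),
            par=ds["par"].values.astype(float),
            kd490=ds["kd490"].values.astype(float),
            valid_days=ds["valid_days"].values.astype(int),
            filled=ds["filled"].values.astype(bool),
        )


def read_composites(in_dir: Path | str) -> List[MonthlyComposite]:
    paths = sorted(Path(in_dir).glob("composite_*.nc"))
    if not paths:
        raise FileNotFoundError(f"no composite_*.nc files under {in_dir}")
    comps = [read_composite(p) for p in paths]
    comps.sort(key=lambda c: (c.year, c.month))
    return comps


def composite_filename(comp: MonthlyComposite) -> str:
    return f"composite_{comp.year:04d}-{comp.month:02d}.nc"


def write_layer_tiff(layer: np.ndarray, path: Path | str) -> Path:
    """Single-band float TIFF on the local metric grid (no georeferencing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(layer, dtype=np.float32))
    return path


def read_layer_tiff(path: Path | str) -> np.ndarray:
    return tifffile.imread(path)


_MATCHUP_COLS = [
    "station_id", "variable", "field_value", "satellite_value",
    "offset_h", "sd_over_mean", "valid",
]


def write_matchups_csv(matchups: Sequence[MatchupPair], path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "station_id": m.station_id,
            "variable": m.variable_name,
            "field_value": m.field_value,
            "satellite_value": m.satellite_value,
            "offset_h": m.time_offset_h,
            "sd_over_mean": m.box_sd_over_mean,
            "valid": m.valid,
        }
        for m in matchups
    ]
    pd.DataFrame(rows, columns=_MATCHUP_COLS).to_csv(path, index=False)
    return path


def read_matchups_csv(path: Path | str) -> List[MatchupPair]:
    df = pd.read_csv(path)
    return [
        MatchupPair(
            station_id=str(r.station_id),
            variable_name=str(r.variable),
            satellite_value=float(r.satellite_value),
            field_value=float(r.field_value),
            time_offset_h=float(r.offset_h),
            box_sd_over_mean=float(r.sd_over_mean),
            valid=bool(r.valid),
        )
        for r in df.itertuples()
    ]


def write_json(obj, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
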