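"""Reading and writing the pipeline's raster and tabular artifacts.

GeoTIFF-style output goes through :mod:`tifffile` with a JSON metadata
payload in the image description; NetCDF goes through :mod:`xarray` with the
scipy backend (classic NetCDF-3).  Spectral libraries travel as CSV or JSON
and area series as CSV, so every artifact round-trips without external
geospatial stacks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from .scenes import CONFOUNDER_CODES, Scene, SceneTruth
from .unmixing import Detection

__all__ = [
    "write_raster",
    "read_raster",
    "write_scene",
    "read_scene",
    "write_detection",
    "read_detection",
]


def write_raster(path, array: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 2-D or (bands, H, W) array as a TIFF with JSON metadata."""
    arr = np.asarray(array)
    tifffile.imwrite(path, arr.astype(np.float32), description=json.dumps(metadata or {}))


def read_raster(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return np.asarray(arr, dtype=float), meta


def _scene_dataset(scene: Scene) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "reflectance": (("wavelength", "y", "x"), scene.bands),
            "valid_mask": (("y", "x"), scene.valid_mask.astype(np.int8)),
        },
        coords={"wavelength": np.asarray(scene.wavelengths, dtype=float)},
        attrs={"pixel_area_km2": scene.pixel_area},
    )
    return ds


def write_scene(path, scene: Scene, with_truth: bool = True) -> None:
    """Scene (and truth, if present) as one classic-NetCDF file."""
    ds = _scene_dataset(scene)
    if with_truth and scene.truth is not None:
        t = scene.truth
        legend = sorted({v for v in t.fa_type_map.ravel() if v})
        code = {name: i for i, name in enumerate(legend)}
        type_codes = np.full(t.fa_mask.shape, -1, dtype=np.int16)
        for name, i in code.items():
            type_codes[t.fa_type_map == name] = i
        ds["truth_fa_mask"] = (("y", "x"), t.fa_mask.astype(np.int8))
        ds["truth_chi"] = (("y", "x"), t.chi_map)
        ds["truth_type_code"] = (("y", "x"), type_codes)
        ds["truth_confounder"] = (("y", "x"), t.confounder_map.astype(np.int8))
        ds.attrs["truth_type_legend"] = json.dumps(legend)
        ds.attrs["confounder_legend"] = json.dumps(CONFOUNDER_CODES)
    ds.to_netcdf(path, engine="scipy")


def read_scene(path) -> Scene:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    truth = None
    if "truth_fa_mask" in ds:
        legend = json.loads(ds.attrs.get("truth_type_legend", "[]"))
        codes = ds["truth_type_code"].values
        type_map = np.full(codes.shape, "", dtype=object)
        for i, name in enumerate(legend):
            type_map[codes == i] = name
        truth = SceneTruth(
            fa_mask=ds["truth_fa_mask"].values.astype(bool),
            fa_type_map=type_map,
            chi_map=ds["truth_chi"].values,
            confounder_map=ds["truth_confounder"].values.astype(np.int8),
        )
    return Scene(
        bands=ds["reflectance"].values,
        wavelengths=tuple(float(w) for w in ds["wavelength"].values),
        pixel_area=float(ds.attrs["pixel_area_km2"]),
        valid_mask=ds["valid_mask"].values.astype(bool),
        truth=truth,
    )


def write_detection(path, det: Detection) -> None:
    """Detection as a 3+1-layer NetCDF with a JSON type legend attribute."""
    ds = xr.Dataset(
        {
            "mask": (("y", "x"), det.mask.astype(np.int8)),
            "chi": (("y", "x"), det.chi),
            "type_code": (("y", "x"), det.fa_type.astype(np.int16)),
            "observed": (("y", "x"), det.observed.astype(np.int8)),
        },
        attrs={
            "type_legend": json.dumps(list(det.type_legend)),
            "chi_mode": det.chi_mode,
            "n_clipped": det.n_clipped,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_detection(path) -> Detection:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    sim = np.full(ds["mask"].shape, np.nan)
    return Detection(
        mask=ds["mask"].values.astype(bool),
        chi=ds["chi"].values,
        fa_type=ds["type_code"].values.astype(np.int16),
        similarity=sim,
        type_legend=tuple(json.loads(ds.attrs["type_legend"])),
        observed=ds["observed"].values.astype(bool),
        n_clipped=int(ds.attrs.get("n_clipped", 0)),
        chi_mode=str(ds.attrs.get("chi_mode", "exact")),
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
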