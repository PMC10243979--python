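"""File formats: HDF5 spectrum cubes, multi-page TIFF maps and stacks,
CSV tables and spectra, JSON reports.

Conventions: 0-based pixel indices, row-major, (row, col) = (y, x).  Cube
HDF5 layout: dataset ``/counts`` with attributes ``gain``, ``offset``,
``pixel_size_um``.  Multi-page map TIFFs carry the element symbol in each
page description; stack TIFFs carry the geometry as JSON on the first page.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile

from .confocal_stack import ConfocalStack
from .errors import FormatError
from .spectral_fit import SpectrumCube
from .spectrum_sim import SimulatedSpectrum

__all__ = [
    "write_cube_h5", "read_cube_h5",
    "write_maps_tiff", "read_maps_tiff",
    "write_stack_tiff", "read_stack_tiff",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_spectrum_h5", "read_spectrum_h5",
    "write_json", "read_json",
]


# --- spectrum cubes (HDF5) -------------------------------------------------

def write_cube_h5(path, cube: SpectrumCube) -> None:
    with h5py.File(path, "w") as handle:
        ds = handle.create_dataset("counts", data=cube.counts)
        ds.attrs["gain"] = cube.gain
        ds.attrs["offset"] = cube.offset
        ds.attrs["pixel_size_um"] = cube.pixel_size_um


def read_cube_h5(path) -> SpectrumCube:
    with h5py.File(path, "r") as handle:
        if "counts" not in handle:
            raise FormatError(f"{path}: missing dataset /counts")
        ds = handle["counts"]
        for attr in ("gain", "offset"):
            if attr not in ds.attrs:
                raise FormatError(f"{path}: /counts missing attribute {attr!r}")
        return SpectrumCube(
            counts=ds[()], gain=float(ds.attrs["gain"]),
            offset=float(ds.attrs["offset"]),
            pixel_size_um=float(ds.attrs.get("pixel_size_um", 1.0)))


# --- element maps (multi-page TIFF, one page per element) ------------------

def write_maps_tiff(path, maps: Mapping[str, np.ndarray],
                    pixel_size_um: float = 1.0) -> None:
    with tifffile.TiffWriter(path) as writer:
        for element, image in maps.items():
            writer.write(
                np.asarray(image, dtype=np.float32),
                description=json.dumps(
                    {"element": element, "pixel_size_um": pixel_size_um}))


def read_maps_tiff(path) -> tuple[dict[str, np.ndarray], float]:
    maps: dict[str, np.ndarray] = {}
    pixel_size = 1.0
    with tifffile.TiffFile(path) as reader:
        for page in reader.pages:
            try:
                meta = json.loads(page.description)
                element = meta["element"]
            except (json.JSONDecodeError, KeyError, TypeError):
                raise FormatError(
                    f"{path}: page description is not element metadata") from None
            pixel_size = float(meta.get("pixel_size_um", 1.0))
            maps[element] = page.asarray().astype(float)
    return maps, pixel_size


# --- confocal stacks (multi-page TIFF, one page per depth plane) -----------

def write_stack_tiff(path, stack: ConfocalStack) -> None:
    meta = {
        "depth_step_um": stack.depth_step_um,
        "geometry_angle_deg": stack.geometry_angle_deg,
        "pixel_size_um": stack.pixel_size_um,
        "probe_depth_um": stack.probe_depth_um,
        "shift_axis": stack.shift_axis,
        "shift_sign": stack.shift_sign,
    }
    with tifffile.TiffWriter(path) as writer:
        for k in range(stack.n_planes):
            writer.write(stack.planes[k].astype(np.float32),
                         description=json.dumps({"plane": k, **meta}))


def read_stack_tiff(path) -> ConfocalStack:
    planes = []
    meta = None
    with tifffile.TiffFile(path) as reader:
        for page in reader.pages:
            if meta is None:
                try:
                    meta = json.loads(page.description)
                except (json.JSONDecodeError, TypeError):
                    raise FormatError(
                        f"{path}: first page carries no geometry metadata"
                    ) from None
            planes.append(page.asarray().astype(float))
    if meta is None or "depth_step_um" not in meta:
        raise FormatError(f"{path}: missing field depth_step_um")
    probe = meta.get("probe_depth_um")
    return ConfocalStack(
        planes=np.stack(planes),
        depth_step_um=float(meta["depth_step_um"]),
        geometry_angle_deg=float(meta.get("geometry_angle_deg", 45.0)),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        probe_depth_um=float(probe) if probe is not None else None,
        shift_axis=int(meta.get("shift_axis", 0)),
        shift_sign=int(meta.get("shift_sign", 1)))


# --- spectra ---------------------------------------------------------------

def write_spectrum_csv(path, spectrum: SimulatedSpectrum) -> None:
    pd.DataFrame({"energy_keV": spectrum.energy_keV,
                  "counts": spectrum.counts}).to_csv(path, index=False)


def read_spectrum_csv(path) -> SimulatedSpectrum:
    table = pd.read_csv(path)
    for column in ("energy_keV", "counts"):
        if column not in table.columns:
            raise FormatError(f"{path}: missing column {column!r}")
    grid = table["energy_keV"].to_numpy(dtype=float)
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
    return SimulatedSpectrum(energy_keV=grid,
                             counts=table["counts"].to_numpy(dtype=float),
                             gain=step, offset=float(grid[0]))


def write_spectrum_h5(path, spectrum: SimulatedSpectrum) -> None:
    with h5py.File(path, "w") as handle:
        ds = handle.create_dataset("counts", data=spectrum.counts)
        ds.attrs["gain"] = spectrum.gain
        ds.attrs["offset"] = spectrum.offset


def read_spectrum_h5(path) -> SimulatedSpectrum:
    with h5py.File(path, "r") as handle:
        if "counts" not in handle:
            raise FormatError(f"{path}: missing dataset /counts")
        ds = handle["counts"]
        counts = ds[()]
        gain = float(ds.attrs["gain"])
        offset = float(ds.attrs["offset"])
    grid = offset + gain * np.arange(len(counts))
    return SimulatedSpectrum(energy_keV=grid, counts=counts,
                             gain=gain, offset=offset)


# --- JSON ------------------------------------------------------------------

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, frozenset):
            return sorted(obj)
        return super().default(obj)


def write_json(path, payload) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path):
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
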