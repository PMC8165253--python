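"""Persistence: SignalSets as HDF5, reconstructed volumes as NIfTI or TIFF.

All stored quantities are SI (meters, seconds, Pa); arrays are written as
float32 and round-trip losslessly at that precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .types import ReconGrid, ReconVolume, ScanGeometry, SignalSet

__all__ = [
    "SchemaError",
    "write_signalset",
    "read_signalset",
    "write_volume",
    "read_volume",
]


class SchemaError(ValueError):
    """A persisted container is missing or violates a required field."""


_SIGNAL_ATTRS = ("fs", "t0", "pitch", "origin", "rep_rate", "wavelength_nm", "seed")


def write_signalset(signals: SignalSet, path: Union[str, Path]) -> None:
    """Write a SignalSet to HDF5: dataset /data [nx, ny, nt] float32 + attrs."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across re-runs
        f.create_dataset(
            "data", data=signals.data.astype(np.float32), track_times=False
        )
        f.attrs["fs"] = signals.fs
        f.attrs["t0"] = signals.t0
        f.attrs["pitch"] = signals.geometry.pitch
        f.attrs["origin"] = signals.geometry.origin
        f.attrs["rep_rate"] = signals.geometry.rep_rate
        f.attrs["wavelength_nm"] = (
            signals.wavelength_nm if signals.wavelength_nm is not None else -1.0
        )
        f.attrs["seed"] = signals.seed if signals.seed is not None else -1


def read_signalset(path: Union[str, Path]) -> SignalSet:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise SchemaError("missing dataset 'data'")
        data = f["data"][()].astype(float)
        if data.ndim != 3:
            raise SchemaError("dataset 'data' must have axes [scan_x, scan_y, time]")
        for name in _SIGNAL_ATTRS:
            if name not in f.attrs:
                raise SchemaError(f"missing attribute {name!r}")
        geometry = ScanGeometry(
            nx=data.shape[0],
            ny=data.shape[1],
            pitch=float(f.attrs["pitch"]),
            origin=np.asarray(f.attrs["origin"], dtype=float),
            rep_rate=float(f.attrs["rep_rate"]),
        )
        wl = float(f.attrs["wavelength_nm"])
        seed = int(f.attrs["seed"])
        return SignalSet(
            data=data,
            fs=float(f.attrs["fs"]),
            t0=float(f.attrs["t0"]),
            geometry=geometry,
            wavelength_nm=wl if wl >= 0 else None,
            seed=seed if seed >= 0 else None,
        )


def _volume_meta(vol: ReconVolume) -> dict:
    return {
        "voxel": vol.grid.voxel,
        "origin": list(map(float, vol.grid.origin)),
        "wavelength_nm": vol.wavelength_nm,
        "envelope": bool(vol.envelope_applied),
    }


def write_volume(vol: ReconVolume, path: Union[str, Path]) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz, meter-scaled affine) or TIFF.

    TIFF stacks are paged along z with the grid metadata in the image
    description; NIfTI carries the voxel size and origin in the affine and the
    wavelength/envelope flags in the header description.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([vol.grid.voxel] * 3 + [1.0])
        affine[:3, 3] = vol.grid.origin
        img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
        img.header.set_xyzt_units(xyz="meter")
        wl = vol.wavelength_nm if vol.wavelength_nm is not None else -1.0
        img.header["descrip"] = f"wl={wl:g};env={int(vol.envelope_applied)}".encode()
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.moveaxis(vol.values, 2, 0).astype(np.float32),
            description=json.dumps(_volume_meta(vol)),
        )
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path: Union[str, Path]) -> ReconVolume:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        values = np.asarray(img.dataobj, dtype=float)
        voxel = float(affine[0, 0])
        origin = affine[:3, 3]
        m = re.match(rb"wl=([^;]+);env=(\d)", bytes(img.header["descrip"]))
        if m is None:
            raise SchemaError("NIfTI header lacks the wl/env description")
        wl = float(m.group(1))
        grid = ReconGrid(shape=values.shape, voxel=voxel, origin=origin)
        return ReconVolume(
            grid=grid,
            values=values,
            wavelength_nm=wl if wl >= 0 else None,
            envelope_applied=bool(int(m.group(2))),
        )
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            values = np.moveaxis(tf.asarray(), 0, 2).astype(float)
            desc = tf.pages[0].tags["ImageDescription"].value
        meta = json.loads(desc)
        grid = ReconGrid(
            shape=values.shape, voxel=float(meta["voxel"]), origin=meta["origin"]
        )
        return ReconVolume(
            grid=grid,
            values=values,
            wavelength_nm=meta["wavelength_nm"],
            envelope_applied=bool(meta["envelope"]),
        )
    raise ValueError(f"unsupported volume format: {path.name}")
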