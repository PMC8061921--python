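"""Reading and writing image stacks and intensity curves.

Stacks round-trip losslessly through HDF5 (dataset ``frames`` with
``frame_interval_s`` and ``voxel_size_mm`` attributes) and are also
supported as 4-D NIfTI, where the frame interval lives in the fourth
pixdim.  Curves round-trip as two-column CSV with an optional JSON
sidecar carrying baseline/QC state.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .curves import ImageSequence, IntensityCurve
from .errors import FormatError

__all__ = ["save_stack", "load_stack", "save_curve", "load_curve"]

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_NIFTI_SUFFIXES = {".nii", ".gz"}


def save_stack(seq: ImageSequence, path: str | Path) -> None:
    """Write a stack as HDF5 or 4-D NIfTI, chosen by file suffix."""
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("frames", data=seq.frames)
            dset.attrs["frame_interval_s"] = seq.frame_interval_s
            dset.attrs["voxel_size_mm"] = seq.voxel_size_mm
        return
    if path.suffix in _NIFTI_SUFFIXES:
        vox = seq.voxel_size_mm
        affine = np.diag([vox, vox, vox, 1.0])
        img = nib.Nifti1Image(seq.frames, affine)
        img.header["pixdim"][4] = seq.frame_interval_s
        img.header.set_xyzt_units(xyz="mm", t="sec")
        nib.save(img, path)
        return
    raise FormatError(f"unsupported stack format: {path.suffix!r}")


def load_stack(path: str | Path) -> ImageSequence:
    """Load a stack saved by :func:`save_stack`.

    Raises :class:`~mpiflow.errors.FormatError` naming the missing
    metadata key when timing or voxel information is absent, and for
    non-4-D data.
    """
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as fh:
            if "frames" not in fh:
                raise FormatError(f"{path}: missing dataset 'frames'")
            dset = fh["frames"]
            for key in ("frame_interval_s", "voxel_size_mm"):
                if key not in dset.attrs:
                    raise FormatError(f"{path}: missing attribute {key!r}")
            frames = np.asarray(dset)
            if frames.ndim != 4:
                raise FormatError(f"{path}: frames must be 4-D, got {frames.ndim}-D")
            return ImageSequence(
                frames=frames,
                frame_interval_s=float(dset.attrs["frame_interval_s"]),
                voxel_size_mm=float(dset.attrs["voxel_size_mm"]),
            )
    if path.suffix in _NIFTI_SUFFIXES:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise FormatError(f"{path}: expected 4-D NIfTI, got {data.ndim}-D")
        dt = float(img.header["pixdim"][4])
        if dt <= 0:
            raise FormatError(f"{path}: missing timing metadata frame_interval")
        vox = float(img.header["pixdim"][1])
        return ImageSequence(frames=data, frame_interval_s=dt, voxel_size_mm=vox)
    raise FormatError(f"unsupported stack format: {path.suffix!r}")


def save_curve(curve: IntensityCurve, path: str | Path, sidecar: bool = True) -> None:
    """Write a curve as CSV (``time_s``, ``intensity``) plus JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": curve.times, "intensity": curve.intensities}).to_csv(
        path, index=False
    )
    if sidecar:
        meta = {
            "interpolation_factor": curve.interpolation_factor,
            "baseline_value": curve.baseline_value,
            "baseline_window": list(curve.baseline_window)
            if curve.baseline_window
            else None,
            "baseline_noise_sd": curve.baseline_noise_sd,
            "is_baseline_subtracted": curve.is_baseline_subtracted,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_curve(path: str | Path) -> IntensityCurve:
    """Load a curve CSV; restores state from the JSON sidecar if present."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    curve = IntensityCurve(
        times=df["time_s"].to_numpy(), intensities=df["intensity"].to_numpy()
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        curve.interpolation_factor = int(meta.get("interpolation_factor", 1))
        curve.baseline_value = meta.get("baseline_value")
        bw = meta.get("baseline_window")
        curve.baseline_window = tuple(bw) if bw else None
        curve.baseline_noise_sd = meta.get("baseline_noise_sd")
        curve.is_baseline_subtracted = bool(meta.get("is_baseline_subtracted", False))
    return curve
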