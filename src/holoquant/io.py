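"""NIfTI and table I/O.

Volumes are written as NIfTI-1 (.nii or .nii.gz) with 32-bit float data,
masks with 8-bit integer data; the voxel spacing and origin live in the
(diagonal) affine. Tables are UTF-8 CSV with '.' decimal and a header
row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import ActivityVolume, VOIMask, VoxelGrid

__all__ = [
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_table",
    "write_json",
]


class VolumeFormatError(ValueError):
    """A volume file is malformed or lacks usable geometry metadata."""


def _grid_from_image(img, path) -> VoxelGrid:
    aff = np.asarray(img.affine, dtype=float)
    lin = aff[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise VolumeFormatError(
            f"{path}: affine has off-diagonal terms; only axis-aligned volumes are supported"
        )
    spacing = np.abs(np.diag(lin))
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"{path}: missing or non-positive voxel spacing in header")
    shape = img.shape
    if len(shape) != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got shape {shape}")
    return VoxelGrid(tuple(shape), tuple(spacing), tuple(aff[:3, 3]))


def _load(path):
    try:
        return nib.load(str(path))
    except Exception as err:  # nibabel raises several header/format errors
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {err}") from err


def read_volume(path, unit: str = "MBq/mL") -> ActivityVolume:
    img = _load(path)
    grid = _grid_from_image(img, path)
    data = np.asarray(img.get_fdata(), dtype=float)
    return ActivityVolume(grid, data, unit=unit)


def write_volume(path, vol: ActivityVolume) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def read_mask(path, label: str = "custom") -> VOIMask:
    img = _load(path)
    grid = _grid_from_image(img, path)
    data = np.asarray(img.get_fdata())
    return VOIMask(grid, data > 0.5, label=label)


def write_mask(path, mask: VOIMask) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def write_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.10g")


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
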