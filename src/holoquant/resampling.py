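"""Nearest-neighbor resampling between voxel grids.

Mirrors the analysis convention of moving reconstructed volumes onto a
high-resolution grid with an affine transform and nearest-neighbor
interpolation: no new values are introduced and means over large VOIs
are preserved, while totals are deliberately always computed as
mean x VOI volume (nearest-neighbor upsampling does not conserve sums).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ActivityVolume, VOIMask, VoxelGrid

__all__ = ["AffineTransform", "resample_nearest", "resample_mask_nearest"]


@dataclass(frozen=True)
class AffineTransform:
    """World-mm to world-mm affine map ``x -> linear @ x + offset``."""

    linear: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    offset: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float)
        off = np.asarray(self.offset, dtype=float)
        if lin.shape != (3, 3) or off.shape != (3,):
            raise ValueError("linear must be 3x3 and offset a 3-vector")
        object.__setattr__(self, "linear", tuple(map(tuple, lin)))
        object.__setattr__(self, "offset", tuple(off))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_flat(cls, twelve: list[float]) -> "AffineTransform":
        """Row-major 9 linear entries followed by the 3 offset entries."""
        v = np.asarray(twelve, dtype=float)
        if v.shape != (12,):
            raise ValueError("expected 12 numbers (row-major 3x3 + offset)")
        return cls(tuple(map(tuple, v[:9].reshape(3, 3))), tuple(v[9:]))

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.linear, dtype=float)

    def inverse_matrix(self) -> np.ndarray:
        mat = self.matrix
        if abs(np.linalg.det(mat)) < 1e-12:
            raise ValueError("affine transform is singular (non-invertible linear part)")
        return np.linalg.inv(mat)


def resample_nearest(
    src: ActivityVolume,
    transform: AffineTransform,
    target_grid: VoxelGrid,
) -> ActivityVolume:
    """Pull a volume onto ``target_grid`` through an affine transform.

    Each target voxel takes the value of the source voxel whose center
    is nearest to the target center mapped through the *inverse*
    transform; targets landing outside the source grid get 0. When two
    source centers are equidistant (fractional index exactly .5) the
    lower index wins, per axis, so the lowest linear index is chosen.
    """
    inv = transform.inverse_matrix()
    off = np.asarray(transform.offset)
    xs = target_grid.axis_coords(0)[:, None, None]
    ys = target_grid.axis_coords(1)[None, :, None]
    zs = target_grid.axis_coords(2)[None, None, :]
    shape = target_grid.shape
    out = np.zeros(shape, dtype=src.values.dtype)
    # source index per axis: world -> inverse affine -> fractional index
    src_origin = np.asarray(src.grid.origin)
    src_spacing = np.asarray(src.grid.spacing)
    idx = []
    valid = np.ones(shape, dtype=bool)
    for ax in range(3):
        w = (
            inv[ax, 0] * (xs - off[0])
            + inv[ax, 1] * (ys - off[1])
            + inv[ax, 2] * (zs - off[2])
        )
        f = (w - src_origin[ax]) / src_spacing[ax]
        # ties at .5 resolve to the lower index
        i = np.ceil(f - 0.5).astype(np.int64)
        valid &= (i >= 0) & (i < src.grid.shape[ax])
        idx.append(np.broadcast_to(i, shape))
    iv = tuple(np.clip(idx[ax], 0, src.grid.shape[ax] - 1) for ax in range(3))
    out = np.where(valid, src.values[iv[0], iv[1], iv[2]], 0)
    return ActivityVolume(target_grid, out, src.unit)


def resample_mask_nearest(
    mask: VOIMask, transform: AffineTransform, target_grid: VoxelGrid
) -> VOIMask:
    """Nearest-neighbor resampling of a boolean mask (values stay binary)."""
    vol = ActivityVolume(mask.grid, mask.mask.astype(float), unit="mask")
    res = resample_nearest(vol, transform, target_grid)
    return VOIMask(target_grid, res.values > 0.5, mask.label)
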