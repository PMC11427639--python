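"""Core spatial containers: voxel grids, scalar volumes, and boolean masks.

All geometry lives in world coordinates measured in millimetres. A
:class:`VoxelGrid` places a regular lattice of voxel *centers* in world
space: index ``(0, 0, 0)`` sits at ``origin`` and index ``(i, j, k)`` at
``origin + spacing * (i, j, k)``. Volumes and masks carry their grid so
that every derived quantity (voxel volume, VOI volume, totals) is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["VoxelGrid", "ActivityVolume", "VOIMask"]


def _triple(x: Iterable[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis.
    spacing : tuple of float
        Voxel edge length per axis in mm; all strictly positive.
    origin : tuple of float
        World coordinate (mm) of the *center* of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", _triple(self.spacing))
        object.__setattr__(self, "origin", _triple(self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def lower_edge(self) -> tuple[float, float, float]:
        """World coordinate of the low corner of the grid's bounding box."""
        return tuple(o - s / 2.0 for o, s in zip(self.origin, self.spacing))  # type: ignore[return-value]

    @property
    def upper_edge(self) -> tuple[float, float, float]:
        return tuple(
            o + s * (n - 0.5) for o, s, n in zip(self.origin, self.spacing, self.shape)
        )  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for an (..., 3) array of world points."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @classmethod
    def centered(
        cls,
        extent_mm: float | tuple[float, float, float],
        spacing_mm: float | tuple[float, float, float],
    ) -> "VoxelGrid":
        """Grid centered on the world origin covering at least ``extent_mm``.

        Shapes are forced odd so that a voxel center sits exactly at the
        world origin; this keeps centered phantoms symmetric on the grid.
        """
        ext = (extent_mm,) * 3 if np.isscalar(extent_mm) else tuple(extent_mm)
        sp = (spacing_mm,) * 3 if np.isscalar(spacing_mm) else tuple(spacing_mm)
        shape = []
        origin = []
        for e, s in zip(ext, sp):
            n = int(np.ceil(e / s))
            if n % 2 == 0:
                n += 1
            shape.append(n)
            origin.append(-s * (n - 1) / 2.0)
        return cls(tuple(shape), tuple(sp), tuple(origin))


def _check_shape(grid: VoxelGrid, arr: np.ndarray, what: str) -> None:
    if tuple(arr.shape) != tuple(grid.shape):
        raise ValueError(f"{what} shape {arr.shape} does not match grid shape {grid.shape}")


@dataclass
class ActivityVolume:
    """Scalar 3-D field on a grid: activity concentration or count density.

    ``unit`` documents the value semantics (``"MBq/mL"``, ``"counts"``,
    ``"cps/mL"``); arithmetic helpers do not convert units.
    """

    grid: VoxelGrid
    values: np.ndarray
    unit: str = "MBq/mL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.grid, self.values, "values")

    @property
    def total(self) -> float:
        """Sum of values times voxel volume (MBq if values are MBq/mL)."""
        return float(self.values.sum()) * self.grid.voxel_volume_ml

    def mean_in(self, mask: "VOIMask") -> float:
        if self.grid != mask.grid:
            raise ValueError("volume and mask are on different grids")
        if not mask.mask.any():
            raise ValueError(f"VOI '{mask.label}' is empty")
        return float(self.values[mask.mask].mean())

    def copy(self) -> "ActivityVolume":
        return ActivityVolume(self.grid, self.values.copy(), self.unit)


@dataclass
class VOIMask:
    """Boolean volume-of-interest aligned to a grid."""

    grid: VoxelGrid
    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_shape(self.grid, self.mask, f"mask '{self.label}'")

    @property
    def volume_ml(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_volume_ml

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "VOIMask") -> "VOIMask":
        return VOIMask(self.grid, self.mask & other.mask, self.label)

    def __or__(self, other: "VOIMask") -> "VOIMask":
        return VOIMask(self.grid, self.mask | other.mask, self.label)
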