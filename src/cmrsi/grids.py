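"""Shared spatial conventions for all reconstruction and simulation code.

Every module in this package uses the same DFT-consistent convention:

* Along axis ``d`` with ``M_d`` voxels, voxel centers sit at the
  FOV-normalized coordinates ``x~_j = (j - floor(M_d/2)) / M_d`` for
  ``j = 0 .. M_d - 1``, so integer k-space coordinates are cycles per FOV.
* Voxels are linearized x-fastest: ``j = ix + Mx*(iy + My*iz)``
  (Fortran ravel order on an (Mx, My, Mz)-shaped array).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "axis_coords", "voxel_centers", "ravel_map", "unravel_map"]


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel grid over a field of view.

    Parameters
    ----------
    shape:
        Number of voxels along (x, y, z).
    fov_mm:
        Field of view along (x, y, z) in millimetres.
    """

    shape: tuple[int, int, int]
    fov_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        if len(self.fov_mm) != 3 or any(f <= 0 for f in self.fov_mm):
            raise ValueError(f"FOV must be three positive lengths, got {self.fov_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.shape))

    def oversampled(self, factor: int) -> "GridSpec":
        """Grid covering the same FOV with ``factor``-times finer voxels."""
        if factor < 1:
            raise ValueError("oversampling factor must be >= 1")
        return GridSpec(tuple(n * factor for n in self.shape), self.fov_mm)

    def centers_normalized(self) -> np.ndarray:
        """Voxel centers in FOV-normalized units, shape (n_voxels, 3)."""
        return voxel_centers(self.shape)

    def centers_mm(self) -> np.ndarray:
        """Voxel centers in millimetres (FOV-centered), shape (n_voxels, 3)."""
        return voxel_centers(self.shape) * np.asarray(self.fov_mm)


def axis_coords(n: int) -> np.ndarray:
    """FOV-normalized center coordinates along one axis: (j - n//2)/n."""
    return (np.arange(n) - n // 2) / n


def voxel_centers(shape: tuple[int, int, int]) -> np.ndarray:
    """All voxel centers in FOV-normalized units, x-fastest linearization."""
    cx, cy, cz = (axis_coords(n) for n in shape)
    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    return np.column_stack(
        [gx.ravel(order="F"), gy.ravel(order="F"), gz.ravel(order="F")]
    )


def ravel_map(volume: np.ndarray) -> np.ndarray:
    """Flatten an (Mx, My, Mz) volume with the package voxel linearization."""
    return np.asarray(volume).ravel(order="F")


def unravel_map(flat: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`ravel_map`."""
    return np.asarray(flat).reshape(shape, order="F")
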