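"""Surface-coil receive sensitivity maps from a discretized Biot-Savart model.

The transmit/receive hardware emulated here is a quadrature pair of
overlapped circular surface loops placed anterior to the chest.  Each
loop is discretized into straight current segments and the magnitude of
the magnetic field per unit current is evaluated at every voxel center.
Close to the wire the magnetostatic 1/r^2 kernel diverges and the
discretized field is not a meaningful sensitivity estimate, so values
within a configurable exclusion radius of any segment are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec

__all__ = ["CoilGeometry", "circular_loop", "default_cardiac_coil", "biot_savart_sensitivity"]

MU0 = 4e-7 * np.pi  # T m / A


@dataclass(frozen=True)
class Loop:
    center_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius_mm: float
    n_segments: int = 64

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("loop radius must be positive")
        if self.n_segments < 8:
            raise ValueError("loops need at least 8 segments")
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("loop normal must have unit length (within 1e-9)")


@dataclass(frozen=True)
class CoilGeometry:
    """A receive coil built from one or more circular current loops."""

    loops: tuple[Loop, ...] = field(default_factory=tuple)

    @property
    def n_channels(self) -> int:
        return len(self.loops)


def circular_loop(
    center_mm: tuple[float, float, float],
    normal: tuple[float, float, float],
    radius_mm: float,
    n_segments: int = 64,
) -> Loop:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return Loop(tuple(float(c) for c in center_mm), tuple(n), float(radius_mm), int(n_segments))


def default_cardiac_coil(n_segments: int = 64) -> CoilGeometry:
    """Two overlapped 15 cm loops anterior to the FOV, normals along +y."""
    r = 75.0
    return CoilGeometry(
        (
            circular_loop((-40.0, -135.0, 0.0), (0.0, 1.0, 0.0), r, n_segments),
            circular_loop((40.0, -135.0, 0.0), (0.0, 1.0, 0.0), r, n_segments),
        )
    )


def _loop_vertices_mm(loop: Loop) -> np.ndarray:
    """Vertices of the polygonal approximation of the loop, shape (n+1, 3)."""
    n = np.asarray(loop.normal, dtype=float)
    # Build an orthonormal frame (u, v, n).
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    theta = np.linspace(0.0, 2.0 * np.pi, loop.n_segments + 1)
    return (
        np.asarray(loop.center_mm)
        + loop.radius_mm * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    )


def _segment_field(points_m: np.ndarray, a_m: np.ndarray, b_m: np.ndarray) -> np.ndarray:
    """Biot-Savart field (T per A) of straight segments a->b at given points.

    points_m: (P, 3); a_m, b_m: (S, 3). Returns (P, 3).
    Uses the exact finite-wire expression
    ``B = mu0 I/(4 pi) (r1 x r2)(|r1|+|r2|) / (|r1||r2|(|r1||r2| + r1.r2))``
    so the only residual error is the polygonal approximation of the loop.
    """
    r1 = points_m[:, None, :] - a_m[None, :, :]  # (P, S, 3)
    r2 = points_m[:, None, :] - b_m[None, :, :]
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    denom = n1 * n2 * (n1 * n2 + np.einsum("psd,psd->ps", r1, r2))
    with np.errstate(divide="ignore", invalid="ignore"):
        db = np.cross(r1, r2) * ((n1 + n2) / denom)[..., None]
    db[~np.isfinite(db)] = 0.0
    return MU0 / (4.0 * np.pi) * db.sum(axis=1)


def _min_distance_to_segments(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimum point-to-segment distance; points (P,3), segments a->b (S,3)."""
    ab = b - a  # (S, 3)
    denom = np.einsum("sd,sd->s", ab, ab)
    ap = points[:, None, :] - a[None, :, :]  # (P, S, 3)
    t = np.clip(np.einsum("psd,sd->ps", ap, ab) / np.maximum(denom, 1e-30), 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=-1).min(axis=1)


def biot_savart_sensitivity(
    coils: CoilGeometry,
    grid: GridSpec,
    exclusion_radius_mm: float = 15.0,
) -> np.ndarray:
    """Per-loop field-magnitude sensitivity at every voxel center.

    Returns an array of shape ``(n_loops, n_voxels)`` (package voxel
    linearization) holding |B| in tesla per ampere.  Voxels closer than
    ``exclusion_radius_mm`` to any wire segment of a loop are zeroed for
    that loop, because the discretized Biot-Savart field is unreliable
    near the conductor.
    """
    points_mm = grid.centers_mm()
    points_m = points_mm * 1e-3
    out = np.zeros((coils.n_channels, grid.n_voxels))
    for i, loop in enumerate(coils.loops):
        verts_mm = _loop_vertices_mm(loop)
        a_mm, b_mm = verts_mm[:-1], verts_mm[1:]
        field_vec = _segment_field(points_m, a_mm * 1e-3, b_mm * 1e-3)
        mag = np.linalg.norm(field_vec, axis=-1)
        if exclusion_radius_mm > 0:
            dist = _min_distance_to_segments(points_mm, a_mm, b_mm)
            mag[dist < exclusion_radius_mm] = 0.0
        out[i] = mag
    return out
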