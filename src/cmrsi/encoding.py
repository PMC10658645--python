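"""Phase-encode schemes: acquisition-weighted, truncated central, and fSLAM.

A phase-encode scheme is an ordered list of k-space coordinates
(cycles per FOV, so integer values land on the nominal DFT grid) with a
positive repeat count R_m per encode.  Acquisition weighting (AW) draws
the repeat pattern from an apodizing window so that central k-space is
averaged more; truncated schemes keep only a central block with uniform
averaging; fSLAM starts from a truncated block and numerically optimizes
the fractional per-axis coordinates to reduce signal leakage between
compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .grids import GridSpec

__all__ = [
    "PhaseEncodeScheme",
    "make_aw_scheme",
    "make_central_scheme",
    "optimize_fslam",
    "FslamResult",
]


@dataclass(frozen=True)
class PhaseEncodeScheme:
    """Ordered k-space coordinates with per-encode repeat counts.

    ``k_coords`` has shape (M', 3) in cycles per FOV; ``repeats`` holds the
    positive integer repeat count R_m of each encode.  ``matrix_shape`` is
    the nominal full phase-encode matrix M per axis.
    """

    k_coords: np.ndarray
    repeats: np.ndarray
    fov_mm: tuple[float, float, float]
    matrix_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        k = np.atleast_2d(np.asarray(self.k_coords, dtype=float))
        r = np.asarray(self.repeats, dtype=int)
        if k.ndim != 2 or k.shape[1] != 3:
            raise ValueError("k_coords must have shape (M', 3)")
        if k.shape[0] != r.shape[0] or k.shape[0] < 1:
            raise ValueError("k_coords and repeats must have equal nonzero length")
        if np.any(r < 1):
            raise ValueError("all repeat counts must be >= 1")
        if len({tuple(row) for row in k}) != k.shape[0]:
            raise ValueError("k-space coordinates must be unique")
        object.__setattr__(self, "k_coords", k)
        object.__setattr__(self, "repeats", r)
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))
        object.__setattr__(self, "matrix_shape", tuple(int(n) for n in self.matrix_shape))

    @property
    def n_encodes(self) -> int:
        """M': the number of distinct phase encodes recorded."""
        return self.k_coords.shape[0]

    def total_readouts(self) -> int:
        """Total number of FID readouts, sum of R_m."""
        return int(self.repeats.sum())

    def is_integer(self) -> bool:
        return bool(np.allclose(self.k_coords, np.round(self.k_coords)))

    def axis_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate vectors if the scheme is a separable grid.

        Raises ``ValueError`` when the k-set is not a Cartesian product of
        three 1D coordinate vectors.
        """
        axes = tuple(np.unique(self.k_coords[:, d]) for d in range(3))
        if int(np.prod([len(a) for a in axes])) != self.n_encodes:
            raise ValueError("scheme is not a separable Cartesian-product grid")
        have = {tuple(row) for row in self.k_coords}
        for kx in axes[0]:
            for ky in axes[1]:
                for kz in axes[2]:
                    if (kx, ky, kz) not in have:
                        raise ValueError("scheme is not a separable Cartesian-product grid")
        return axes

    # -- CSV round trip (kx, ky, kz in cycles/FOV plus repeats) ------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "kx": self.k_coords[:, 0],
                "ky": self.k_coords[:, 1],
                "kz": self.k_coords[:, 2],
                "repeats": self.repeats,
            }
        )
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fov_mm: tuple[float, float, float],
        matrix_shape: tuple[int, int, int],
    ) -> "PhaseEncodeScheme":
        df = pd.read_csv(path)
        k = df[["kx", "ky", "kz"]].to_numpy(dtype=float)
        return cls(k, df["repeats"].to_numpy(dtype=int), fov_mm, matrix_shape)


# ---------------------------------------------------------------------------
# Windows for acquisition weighting.  Each maps integer k (cycles/FOV) on an
# axis of nominal size M to a weight in (0, 1] with w(0) = 1.
# ---------------------------------------------------------------------------

def _hamming(k: np.ndarray, m: int) -> np.ndarray:
    return 0.54 + 0.46 * np.cos(2.0 * np.pi * k / m) if m > 1 else np.ones_like(k, dtype=float)


def _hann(k: np.ndarray, m: int) -> np.ndarray:
    # Offset floor keeps w > 0 at the k-space edge so max(1, round(.)) applies.
    return 0.5 + 0.5 * np.cos(2.0 * np.pi * k / m) if m > 1 else np.ones_like(k, dtype=float)


def _uniform(k: np.ndarray, m: int) -> np.ndarray:
    return np.ones_like(np.asarray(k), dtype=float)


_WINDOWS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "hamming": _hamming,
    "hann": _hann,
    "uniform": _uniform,
}


def _axis_k(m: int) -> np.ndarray:
    """Integer k values on a full axis of size m: -floor(m/2) .. ceil(m/2)-1."""
    return np.arange(m) - m // 2


def make_aw_scheme(
    matrix_shape: tuple[int, int, int],
    center_averages: int = 4,
    weighting: str = "hamming",
    fov_mm: tuple[float, float, float] = (240.0, 240.0, 200.0),
    omit_zero: bool = False,
) -> PhaseEncodeScheme:
    """Acquisition-weighted scheme over the full integer k-space matrix.

    The repeat count at each k is ``round(center_averages * w(k))`` with a
    separable window ``w`` normalized to 1 at k = 0.  By default repeats are
    floored at 1 so every matrix point is acquired; with ``omit_zero`` the
    hard-threshold variant drops encodes whose rounded repeat count is 0.
    """
    if center_averages < 1:
        raise ValueError("center_averages must be >= 1")
    try:
        window = _WINDOWS[weighting]
    except KeyError:
        raise ValueError(
            f"unknown weighting {weighting!r}; supported: {sorted(_WINDOWS)}"
        ) from None
    axes_k = [_axis_k(m) for m in matrix_shape]
    axes_w = [window(k, m) for k, m in zip(axes_k, matrix_shape)]
    gx, gy, gz = np.meshgrid(*axes_k, indexing="ij")
    wx, wy, wz = np.meshgrid(*axes_w, indexing="ij")
    k = np.column_stack(
        [gx.ravel(order="F"), gy.ravel(order="F"), gz.ravel(order="F")]
    ).astype(float)
    w = (wx * wy * wz).ravel(order="F")
    r = np.round(center_averages * w).astype(int)
    if omit_zero:
        keep = r > 0
        k, r = k[keep], r[keep]
    else:
        r = np.maximum(r, 1)
    return PhaseEncodeScheme(k, r, fov_mm, tuple(matrix_shape))


def make_central_scheme(
    matrix_shape: tuple[int, int, int],
    sub_shape: tuple[int, int, int] = (4, 4, 4),
    averages: int = 6,
    fov_mm: tuple[float, float, float] = (240.0, 240.0, 200.0),
) -> PhaseEncodeScheme:
    """Central truncated block of integer k-space with uniform averaging.

    The block keeps the sub_shape integer coordinates nearest the k-space
    origin, per axis ``k in {-s//2, ..., s - s//2 - 1}`` (DFT-consistent).
    """
    if any(s > m for s, m in zip(sub_shape, matrix_shape)):
        raise ValueError(f"sub_shape {sub_shape} exceeds matrix {matrix_shape}")
    if averages < 1:
        raise ValueError("averages must be >= 1")
    axes_k = [_axis_k(s) for s in sub_shape]
    gx, gy, gz = np.meshgrid(*axes_k, indexing="ij")
    k = np.column_stack(
        [gx.ravel(order="F"), gy.ravel(order="F"), gz.ravel(order="F")]
    ).astype(float)
    r = np.full(k.shape[0], int(averages))
    return PhaseEncodeScheme(k, r, fov_mm, tuple(matrix_shape))


# ---------------------------------------------------------------------------
# fSLAM: fractional k-space coordinate optimization
# ---------------------------------------------------------------------------

@dataclass
class FslamResult:
    """Outcome of the fractional-coordinate optimization."""

    scheme: PhaseEncodeScheme
    cost_initial: float
    cost_final: float
    n_evaluations: int
    converged: bool
    message: str = ""


def _fslam_cost_factory(
    init: PhaseEncodeScheme,
    axis_index: np.ndarray,
    axis_len: tuple[int, int, int],
    mask,
    target_id: int,
    sensitivity: np.ndarray | None,
    w_leak: float,
    w_uniform: float,
):
    # Imported here: recon/srf use PhaseEncodeScheme, avoid a module cycle.
    from .recon import build_pe_matrix, compress_compartments
    from .srf import compute_srf

    grid = GridSpec(mask.label_map.shape, mask.fov_mm)
    target_pos = mask.compartment_ids.index(target_id)
    labels_flat = np.asarray(mask.label_map).ravel(order="F")
    in_target = labels_flat == target_id
    outside = ~in_target
    sens = None if sensitivity is None else np.asarray(sensitivity).ravel(order="F")
    nx, ny, nz = axis_len

    def scheme_from_params(p: np.ndarray) -> PhaseEncodeScheme:
        vx, vy, vz = p[:nx], p[nx : nx + ny], p[nx + ny :]
        k = np.column_stack(
            [vx[axis_index[:, 0]], vy[axis_index[:, 1]], vz[axis_index[:, 2]]]
        )
        return PhaseEncodeScheme(k, init.repeats, init.fov_mm, init.matrix_shape)

    def cost(p: np.ndarray) -> float:
        scheme = scheme_from_params(p)
        pe = build_pe_matrix(scheme, grid)
        op = compress_compartments(pe, mask, scheme=scheme)
        beta = compute_srf(op)[target_pos].values.ravel(order="F")
        mag = np.abs(beta) if sens is None else np.abs(beta) * sens
        leak = float(np.sum(mag[outside] ** 2))
        bt = beta[in_target]
        uniform = float(np.mean(np.abs(bt - bt.mean()) ** 2)) if bt.size else 0.0
        return w_leak * leak + w_uniform * uniform

    return scheme_from_params, cost


def optimize_fslam(
    init: PhaseEncodeScheme,
    mask,
    target_id: int = 2,
    sensitivity: np.ndarray | None = None,
    w_leak: float = 1.0,
    w_uniform: float = 1.0,
    bound_halfwidth: float = 1.0,
    method: str = "Powell",
    maxiter: int | None = None,
) -> FslamResult:
    """Optimize the fractional per-axis k-space coordinates of a scheme.

    The scheme must be a separable Cartesian-product grid; the free
    parameters are the concatenated per-axis coordinate vectors (4+4+4 = 12
    for a 4x4x4 block).  The cost is
    ``w_leak * sum_{x outside target} |beta_target(x)|^2``
    (optionally receive-sensitivity weighted) plus
    ``w_uniform * var_{x in target} beta_target(x)``,
    with the spatial response function beta evaluated on the mask grid by a
    SLAM operator built at the candidate coordinates.  Coordinates are
    bounded within ``bound_halfwidth`` cycles/FOV of their initial values;
    repeats and readout totals are unchanged.
    """
    axes = init.axis_vectors()  # raises on non-separable input
    axis_len = tuple(len(a) for a in axes)
    axis_index = np.column_stack(
        [np.searchsorted(axes[d], init.k_coords[:, d]) for d in range(3)]
    )
    if target_id not in mask.compartment_ids:
        raise ValueError(f"target compartment {target_id} not present in mask")
    scheme_from_params, cost = _fslam_cost_factory(
        init, axis_index, axis_len, mask, target_id, sensitivity, w_leak, w_uniform
    )
    p0 = np.concatenate(axes)
    bounds = [(p - bound_halfwidth, p + bound_halfwidth) for p in p0]
    c0 = cost(p0)
    n_eval = 0

    def counted(p):
        nonlocal n_eval
        n_eval += 1
        return cost(p)

    options: dict = {}
    if maxiter is not None:
        options["maxiter"] = maxiter
    res = minimize(counted, p0, method=method, bounds=bounds, options=options)
    if res.fun < c0 and np.isfinite(res.fun):
        best_p, best_c, ok = np.asarray(res.x), float(res.fun), True
    else:  # no strict improvement over the start: keep the initial scheme
        best_p, best_c, ok = p0, c0, bool(res.success)
    try:
        scheme = scheme_from_params(best_p)
    except ValueError as exc:  # duplicate coordinates after optimization
        raise RuntimeError(
            f"fSLAM optimization produced an invalid scheme: {exc}"
        ) from exc
    return FslamResult(
        scheme=scheme,
        cost_initial=c0,
        cost_final=best_c,
        n_evaluations=n_eval,
        converged=ok and bool(res.success),
        message=str(res.message),
    )
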