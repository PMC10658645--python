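"""Compartment (SLAM/SLIM) and Fourier (FT-MRS) reconstruction.

SLAM discretizes the MRSI signal equation on the acquisition grid and
compresses the resulting DFT encoding matrix by summing its columns
within each user-defined compartment (per-voxel-mean normalization by
default); SLIM instead evaluates the continuous-FT integral of the
encoding basis over each compartment volume in closed form (separable
per-axis sinc factors).  Both operators carry the per-encode repeat
count R_m as a row weighting so that summed-repeat
acquisition-weighted data can be reconstructed directly.  Each system
is solved with the Moore-Penrose pseudoinverse H of the compressed
matrix; reconstruction is then the matrix product of H with the
acquired time-domain data followed by an FFT along time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .encoding import PhaseEncodeScheme
from .grids import GridSpec, ravel_map
from .phantom import KSpaceData

__all__ = [
    "CompartmentMask",
    "ReconOperator",
    "CompartmentSpectra",
    "VoxelSpectra",
    "build_pe_matrix",
    "compress_compartments",
    "build_g_matrix",
    "slam_reconstruct",
    "slim_reconstruct",
    "compartment_noise_sd",
    "ft_mrs_reconstruct",
    "estimate_noise_cov",
    "wsvd_combine",
    "spectrum_from_fid",
]

#: condition number above which a rank-deficiency warning is attached
CONDITION_WARNING = 1.0e8


@dataclass(frozen=True)
class CompartmentMask:
    """Disjoint compartments as an integer label map on the recon grid."""

    label_map: np.ndarray
    compartment_ids: list[int]
    fov_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.label_map)
        if arr.ndim != 3:
            raise ValueError("label_map must be a 3D volume")
        if len(self.compartment_ids) < 1:
            raise ValueError("at least one compartment is required")
        present = set(np.unique(arr).tolist())
        for c in self.compartment_ids:
            if c not in present:
                raise ValueError(f"compartment {c} does not occur in the label map")
        object.__setattr__(self, "label_map", arr)
        object.__setattr__(self, "compartment_ids", [int(c) for c in self.compartment_ids])
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_ids)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.label_map.shape, self.fov_mm)

    def voxel_counts(self) -> np.ndarray:
        flat = ravel_map(self.label_map)
        return np.array([np.count_nonzero(flat == c) for c in self.compartment_ids])

    @classmethod
    def from_phantom(cls, phantom, compartment_ids: list[int] | None = None) -> "CompartmentMask":
        ids = compartment_ids if compartment_ids is not None else phantom.compartment_labels
        return cls(phantom.label_map, list(ids), phantom.grid.fov_mm)


@dataclass(frozen=True)
class ReconOperator:
    """A compressed encoding matrix and its pseudoinverse.

    ``encoding_matrix`` is the (M' x C) compartment-compressed phase-encode
    matrix (SLAM) or the continuous-FT G matrix (SLIM); ``pseudoinverse``
    is its (C x M') Moore-Penrose pseudoinverse H with H @ encoding_matrix
    = I for full column rank.
    """

    kind: str  # "SLAM" | "SLIM"
    encoding_matrix: np.ndarray
    pseudoinverse: np.ndarray
    scheme: PhaseEncodeScheme
    mask: CompartmentMask
    compartment_sizes: np.ndarray
    normalization: str = "per_voxel_mean"
    condition_number: float = np.nan
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_compartments(self) -> int:
        return self.encoding_matrix.shape[1]


def _pinv_with_condition(a: np.ndarray) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """SVD pseudoinverse with rank tolerance max(M',C)*eps*sigma_max."""
    u, s, vh = linalg.svd(a, full_matrices=False)
    tol = max(a.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    notes: tuple[str, ...] = ()
    if not np.any(keep):
        return np.zeros(a.T.shape, dtype=complex), np.inf, ("encoding matrix is zero",)
    cond = float(s[0] / s[keep][-1])
    if np.count_nonzero(keep) < a.shape[1]:
        notes = (f"rank-deficient encoding matrix (rank {np.count_nonzero(keep)} of {a.shape[1]})",)
    elif cond > CONDITION_WARNING:
        notes = (f"ill-conditioned encoding matrix (condition number {cond:.3g})",)
    sinv = np.zeros_like(s)
    sinv[keep] = 1.0 / s[keep]
    h = (vh.conj().T * sinv) @ u.conj().T
    return h, cond, notes


def build_pe_matrix(scheme: PhaseEncodeScheme, grid: GridSpec) -> np.ndarray:
    """Full (M' x n_voxels) phase-encode matrix, R_m-weighted rows.

    Entry (m, j) is ``R_m exp(-i 2 pi k_m . x~_j)`` with x~_j the
    FOV-normalized voxel center; columns follow the package x-fastest
    voxel linearization.
    """
    if tuple(scheme.fov_mm) != tuple(grid.fov_mm):
        raise ValueError("scheme and grid FOV differ")
    centers = grid.centers_normalized()
    return scheme.repeats[:, None] * np.exp(-2j * np.pi * (scheme.k_coords @ centers.T))


def compress_compartments(
    pe: np.ndarray,
    mask: CompartmentMask,
    scheme: PhaseEncodeScheme | None = None,
    normalization: str = "per_voxel_mean",
) -> ReconOperator:
    """Compress PE columns into compartments and pseudoinvert (SLAM).

    Column c of the compressed matrix is the per-voxel mean of the PE
    columns whose voxels belong to compartment c; voxels outside every
    listed compartment are excluded.  The ``normalization`` flag selects
    the scale of the reconstructed spectra: "per_voxel_mean" (default)
    reports each compartment on the scale of a single voxel spectrum,
    "total" reports the compartment-integrated signal.
    """
    flat = ravel_map(mask.label_map)
    if pe.shape[1] != flat.size:
        raise ValueError(f"PE has {pe.shape[1]} columns but mask grid has {flat.size} voxels")
    if normalization not in ("per_voxel_mean", "total"):
        raise ValueError("normalization must be 'per_voxel_mean' or 'total'")
    cols = []
    counts = []
    for c in mask.compartment_ids:
        sel = flat == c
        n_c = int(np.count_nonzero(sel))
        if n_c == 0:
            raise ValueError(f"compartment {c} is empty on the reconstruction grid")
        cols.append(pe[:, sel].sum(axis=1) / n_c)
        counts.append(n_c)
    a = np.column_stack(cols)
    h, cond, notes = _pinv_with_condition(a)
    for note in notes:
        warnings.warn(note, RuntimeWarning, stacklevel=2)
    return ReconOperator(
        kind="SLAM",
        encoding_matrix=a,
        pseudoinverse=h,
        scheme=scheme,
        mask=mask,
        compartment_sizes=np.asarray(counts),
        normalization=normalization,
        condition_number=cond,
        warnings=notes,
    )


def build_g_matrix(
    scheme: PhaseEncodeScheme,
    mask: CompartmentMask,
    normalization: str = "per_voxel_mean",
) -> ReconOperator:
    """Continuous-FT compartment encoding matrix G and pseudoinverse (SLIM).

    ``g_mc = R_m sum_{j in comp c} prod_d w_d sinc(k_d w_d)
    exp(-i 2 pi k_m . x~_j)`` evaluates the exact integral of the CFT basis
    over each voxel of the compartment (w_d the FOV-normalized voxel
    width); columns are divided by the compartment volume so G is directly
    comparable with the compressed SLAM matrix.  The ``normalization``
    flag selects the output scale exactly as in
    :func:`compress_compartments`.
    """
    if tuple(scheme.fov_mm) != tuple(mask.fov_mm):
        raise ValueError("scheme and mask FOV differ")
    if normalization not in ("per_voxel_mean", "total"):
        raise ValueError("normalization must be 'per_voxel_mean' or 'total'")
    grid = mask.grid
    widths = np.array([1.0 / n for n in grid.shape])
    centers = grid.centers_normalized()
    flat = ravel_map(mask.label_map)
    # per-encode voxel-integral prefactor: prod_d w_d sinc(k_d w_d)
    sinc_factor = np.prod(widths[None, :] * np.sinc(scheme.k_coords * widths[None, :]), axis=1)
    phase = np.exp(-2j * np.pi * (scheme.k_coords @ centers.T))  # (M', n_vox)
    voxel_volume = float(np.prod(widths))
    cols = []
    counts = []
    for c in mask.compartment_ids:
        sel = flat == c
        n_c = int(np.count_nonzero(sel))
        if n_c == 0:
            raise ValueError(f"compartment {c} is empty on the reconstruction grid")
        col = scheme.repeats * sinc_factor * phase[:, sel].sum(axis=1)
        cols.append(col / (n_c * voxel_volume))
        counts.append(n_c)
    g = np.column_stack(cols)
    h, cond, notes = _pinv_with_condition(g)
    for note in notes:
        warnings.warn(note, RuntimeWarning, stacklevel=2)
    return ReconOperator(
        kind="SLIM",
        encoding_matrix=g,
        pseudoinverse=h,
        scheme=scheme,
        mask=mask,
        compartment_sizes=np.asarray(counts),
        normalization=normalization,
        condition_number=cond,
        warnings=notes,
    )


@dataclass(frozen=True)
class CompartmentSpectra:
    """Separated per-compartment time signals and their spectra."""

    compartment_ids: list[int]
    time_signals: np.ndarray  # complex (C, N)
    spectra: np.ndarray  # complex (C, N), FFT of time_signals (fftshifted)
    dwell_s: float
    normalization: str

    def frequency_axis_hz(self) -> np.ndarray:
        n = self.time_signals.shape[1]
        return np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell_s))

    def compartment(self, compartment_id: int) -> np.ndarray:
        return self.time_signals[self.compartment_ids.index(compartment_id)]


def spectrum_from_fid(fid: np.ndarray) -> np.ndarray:
    """The package-wide time->frequency convention: fftshifted FFT."""
    return np.fft.fftshift(np.fft.fft(np.asarray(fid), axis=-1), axes=-1)


def _solve(kdata: KSpaceData, op: ReconOperator, kind: str) -> CompartmentSpectra:
    if op.kind != kind:
        raise ValueError(f"operator kind {op.kind} does not match requested {kind}")
    if op.scheme is not None and kdata.scheme.n_encodes != op.encoding_matrix.shape[0]:
        raise ValueError("data scheme does not match operator scheme")
    if op.scheme is not None and not np.array_equal(kdata.scheme.k_coords, op.scheme.k_coords):
        raise ValueError("data scheme k-coordinates do not match operator scheme")
    if kdata.n_channels != 1:
        raise ValueError("reconstruct expects single-channel (combined) data")
    # The compressed columns are per-voxel means, so H @ data solves for the
    # compartment-integrated signal; the per-voxel-mean output convention
    # rescales each compartment to the scale of a single voxel spectrum.
    xi = op.pseudoinverse @ kdata.data[0]
    if op.normalization == "per_voxel_mean":
        xi = xi / op.compartment_sizes[:, None]
    return CompartmentSpectra(
        compartment_ids=list(op.mask.compartment_ids),
        time_signals=xi,
        spectra=spectrum_from_fid(xi),
        dwell_s=kdata.dwell_s,
        normalization=op.normalization,
    )


def slam_reconstruct(kdata: KSpaceData, op: ReconOperator) -> CompartmentSpectra:
    """Solve the compressed SLAM system with the pseudoinverse H."""
    return _solve(kdata, op, "SLAM")


def slim_reconstruct(kdata: KSpaceData, op: ReconOperator) -> CompartmentSpectra:
    """Solve the SLIM system H G xi = H s."""
    return _solve(kdata, op, "SLIM")


def compartment_noise_sd(op: ReconOperator, noise_sd_per_average: float) -> np.ndarray:
    """Closed-form complex noise SD of each reconstructed compartment signal.

    Summed-repeat data carry complex noise SD ``sigma * sqrt(R_m)`` per
    encode, so the reconstruction applying the effective matrix H_eff
    (the pseudoinverse, rescaled per the output normalization) yields
    compartment noise SDs ``sigma * ||row_c(H_eff W)||_2`` with
    ``W = diag(sqrt(R_m))``.
    """
    h_eff = op.pseudoinverse
    if op.normalization == "per_voxel_mean":
        h_eff = h_eff / op.compartment_sizes[:, None]
    w = np.sqrt(op.scheme.repeats.astype(float))
    return noise_sd_per_average * np.linalg.norm(h_eff * w[None, :], axis=1)


# ---------------------------------------------------------------------------
# FT-MRS voxel reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelSpectra:
    """Per-voxel FIDs and spectra from the Fourier reconstruction."""

    grid: GridSpec
    fids: np.ndarray  # complex (Mx, My, Mz, N)
    spectra: np.ndarray  # complex (Mx, My, Mz, N)
    dwell_s: float

    def voxel(self, index: tuple[int, int, int]) -> np.ndarray:
        """FID of one voxel (e.g. the caller-selected midseptal voxel)."""
        return self.fids[tuple(int(i) for i in index)]


def ft_mrs_reconstruct(kdata: KSpaceData, grid: GridSpec | None = None) -> VoxelSpectra:
    """Inverse-DFT voxel reconstruction of integer-k phase-encoded data.

    Missing encodes are zero-filled; summed-repeat data are transformed
    as-is so acquisition weighting acts as a k-space apodization (no
    division by R_m).  Fractional k-space coordinates are rejected because
    the DFT is undefined for them.
    """
    scheme = kdata.scheme
    if not scheme.is_integer():
        raise ValueError("FT-MRS requires integer k-space coordinates")
    if kdata.n_channels != 1:
        raise ValueError("ft_mrs_reconstruct expects single-channel (combined) data")
    if grid is None:
        grid = GridSpec(scheme.matrix_shape, scheme.fov_mm)
    shape = grid.shape
    n_time = kdata.n_time
    cube = np.zeros(shape + (n_time,), dtype=complex)
    k_int = np.round(scheme.k_coords).astype(int)
    for m, (kx, ky, kz) in enumerate(k_int):
        idx = (kx + shape[0] // 2, ky + shape[1] // 2, kz + shape[2] // 2)
        if any(not 0 <= i < n for i, n in zip(idx, shape)):
            raise ValueError(f"encode k={tuple(k_int[m])} falls outside the {shape} matrix")
        cube[idx] = kdata.data[0, m]
    # Per-axis inverse DFT consistent with centers x~_j = (j - n//2)/n and
    # integer k in -n//2 .. n - n//2 - 1.
    out = cube
    for axis, n in enumerate(shape):
        kvals = np.arange(n) - n // 2
        xvals = (np.arange(n) - n // 2) / n
        b = np.exp(2j * np.pi * np.outer(xvals, kvals)) / n  # (j, k)
        out = np.moveaxis(np.tensordot(b, out, axes=([1], [axis])), 0, axis)
    return VoxelSpectra(grid=grid, fids=out, spectra=spectrum_from_fid(out), dwell_s=kdata.dwell_s)


# ---------------------------------------------------------------------------
# Multi-coil combination
# ---------------------------------------------------------------------------

def estimate_noise_cov(kdata: KSpaceData, tail_fraction: float = 0.25) -> np.ndarray:
    """Channel noise covariance from the signal-poor FID tail."""
    n_tail = max(2, int(round(kdata.n_time * tail_fraction)))
    x = kdata.data[:, :, -n_tail:].reshape(kdata.n_channels, -1)
    x = x - x.mean(axis=1, keepdims=True)
    return (x @ x.conj().T) / (x.shape[1] - 1)


def wsvd_combine(kdata: KSpaceData, noise_cov: np.ndarray | None = None) -> KSpaceData:
    """Noise-whitened SVD combination of coil channels.

    Channels are whitened with the inverse Cholesky factor of the noise
    covariance, stacked as a (channels x samples) matrix, and replaced by
    the rank-1 SVD approximation: the combined FID is the dominant right
    singular vector scaled by the dominant singular value (preserving the
    total signal energy of the rank-1 term) and phased to follow the
    dominant whitened channel.
    """
    if kdata.n_channels == 1:
        return kdata
    cov = estimate_noise_cov(kdata) if noise_cov is None else np.asarray(noise_cov)
    if not np.allclose(cov, cov.conj().T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("noise covariance must be Hermitian")
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("noise covariance must be positive-definite") from exc
    x = kdata.data.reshape(kdata.n_channels, -1)
    xw = linalg.solve_triangular(chol, x, lower=True)
    u, s, vh = linalg.svd(xw, full_matrices=False)
    combined = s[0] * vh[0]
    dominant = int(np.argmax(np.abs(u[:, 0])))
    combined = combined * np.exp(1j * np.angle(u[dominant, 0]))
    out = combined.reshape(1, kdata.scheme.n_encodes, kdata.n_time)
    return KSpaceData(
        scheme=kdata.scheme,
        data=out,
        dwell_s=kdata.dwell_s,
        noise_sd_per_average=kdata.noise_sd_per_average,
    )
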