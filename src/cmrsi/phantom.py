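"""Digital 3D cardiac phantom and phase-encoded multi-coil forward model.

The phantom voxelizes three tissue compartments on the acquisition FOV:
a spheroidal heart, a curved chest-wall slab adjacent to the anterior
edge, and background "other" tissue, all inside an elliptical body whose
exterior is flagged with the label -1.  Each compartment carries a set
of Lorentzian 31P resonances (PCr, gamma/alpha/beta-ATP, 2,3-DPG
doublet, PDE) with frequencies in Hz relative to PCr at 0.  Smooth
polynomial B0 frequency-offset and phase maps plus relative transmit
and spin-density maps provide the spatial inhomogeneities the
reconstruction algorithms are sensitive to.

The forward model evaluates the phase-encoded signal of the voxelized
spin density: for encode m with repeat count R_m, the stored (summed,
not averaged) signal is ``R_m * sum_x sens(x) fid_x(t) exp(-i 2 pi
k_m . x~)`` plus R_m independent draws of circular complex white noise,
so acquisition-weighted schemes naturally acquire k-dependent noise
variance R_m sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coils import CoilGeometry, biot_savart_sensitivity
from .encoding import PhaseEncodeScheme
from .grids import GridSpec, ravel_map

__all__ = [
    "ResonanceParams",
    "Phantom",
    "PhantomConfig",
    "KSpaceData",
    "default_compartment_spectra",
    "make_cardiac_phantom",
    "voxel_fid",
    "all_voxel_fids",
    "forward_encode",
]

# Compartment labels
OUTSIDE, OTHER, CHEST_WALL, HEART = -1, 0, 1, 2

_AXES = "xyz"


@dataclass(frozen=True)
class ResonanceParams:
    """One Lorentzian line: amplitude, frequency offset, FWHM and phase."""

    name: str
    amplitude: float
    frequency_hz: float
    linewidth_hz: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")
        if self.linewidth_hz <= 0:
            raise ValueError(f"{self.name}: linewidth must be > 0")


def default_compartment_spectra() -> dict[int, list[ResonanceParams]]:
    """Default 31P spectra per compartment (amplitudes in arbitrary units).

    Frequencies are Hz offsets from PCr at 7 T (~120.3 Hz per ppm).  The
    heart carries the full metabolite set including the blood-pool 2,3-DPG
    doublet; the chest wall has a higher PCr/ATP ratio and no blood signal;
    "other" tissue contributes only weak background signal.
    """
    heart = [
        ResonanceParams("PCr", 2.0, 0.0, 40.0),
        ResonanceParams("gamma-ATP", 1.0, -305.0, 45.0),
        ResonanceParams("alpha-ATP", 1.0, -905.0, 45.0),
        ResonanceParams("beta-ATP", 1.0, -1940.0, 55.0),
        ResonanceParams("2,3-DPG2", 0.5, 640.0, 50.0),
        ResonanceParams("2,3-DPG3", 0.5, 755.0, 50.0),
        ResonanceParams("PDE", 0.3, 320.0, 55.0),
    ]
    chest = [
        ResonanceParams("PCr", 4.0, 0.0, 35.0),
        ResonanceParams("gamma-ATP", 1.0, -305.0, 40.0),
        ResonanceParams("alpha-ATP", 1.0, -905.0, 40.0),
        ResonanceParams("beta-ATP", 1.0, -1940.0, 50.0),
    ]
    other = [
        ResonanceParams("PCr", 0.25, 0.0, 50.0),
        ResonanceParams("gamma-ATP", 0.1, -305.0, 55.0),
        ResonanceParams("alpha-ATP", 0.1, -905.0, 55.0),
        ResonanceParams("beta-ATP", 0.1, -1940.0, 60.0),
    ]
    return {HEART: heart, CHEST_WALL: chest, OTHER: other}


_COMPARTMENT_NAMES = {"heart": HEART, "chest_wall": CHEST_WALL, "other": OTHER}


@dataclass(frozen=True)
class Phantom:
    """Voxelized ground truth: labels, spectra, field and density maps."""

    grid: GridSpec
    label_map: np.ndarray  # int, (Mx, My, Mz); -1 marks outside the body
    resonances: dict[int, list[ResonanceParams]]
    delta_f_map: np.ndarray  # Hz
    phase_map: np.ndarray  # rad
    b1_tx_map: np.ndarray  # relative transmit scale
    density_map: np.ndarray  # relative spin density

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("label_map", "delta_f_map", "phase_map", "b1_tx_map", "density_map"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.density_map < 0):
            raise ValueError("density_map must be non-negative")
        if np.any(self.b1_tx_map < 0):
            raise ValueError("b1_tx_map must be non-negative")
        present = set(np.unique(self.label_map).tolist())
        missing = [c for c in self.resonances if c not in present]
        # A compartment configured with spectra may legitimately be empty
        # (degenerate geometry); only warn through absence of signal.
        del missing

    @property
    def compartment_labels(self) -> list[int]:
        labels = np.unique(self.label_map)
        return [int(c) for c in labels if c != OUTSIDE]

    def compartment_voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.label_map == label))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, spectra and field-map configuration of the digital phantom.

    Lengths are millimetres in FOV-centered coordinates (voxel centers span
    ``[-FOV/2, FOV/2)``).  ``b0_peak_hz`` / ``phase_peak_rad`` scale smooth
    second-order polynomial inhomogeneity maps (0 = homogeneous fields).
    The optional shaped-excitation response multiplies resonance amplitudes
    by a Gaussian frequency profile; the default is a flat response.
    """

    grid_shape: tuple[int, int, int] = (8, 16, 8)
    fov_mm: tuple[float, float, float] = (240.0, 240.0, 200.0)
    heart_center_mm: tuple[float, float, float] = (0.0, -25.0, 0.0)
    heart_semiaxes_mm: tuple[float, float, float] = (45.0, 50.0, 40.0)
    chest_wall_standoff_mm: float = 5.0
    chest_wall_thickness_mm: float = 22.0
    chest_wall_bow_mm: float = 15.0
    body_semiaxes_mm: tuple[float, float, float] = (112.0, 118.0, 220.0)
    b0_peak_hz: float = 0.0
    phase_peak_rad: float = 0.0
    trim_heart_base_slices: int = 0
    spectra: dict[str, list[ResonanceParams]] | None = None
    excitation_center_hz: float | None = None
    excitation_bandwidth_hz: float | None = None


def _smooth_poly(grid: GridSpec, coeff_seed: int) -> np.ndarray:
    """A fixed smooth second-order polynomial on the grid, max |.| = 1."""
    x, y, z = (c.reshape(grid.shape, order="F") for c in grid.centers_normalized().T * 2.0)
    if coeff_seed == 0:
        p = 0.9 * x + 0.7 * y - 0.5 * z + 0.6 * x * y - 0.4 * z**2 + 0.3 * x**2
    else:
        p = 0.5 * x - 0.8 * y + 0.6 * z + 0.4 * y * z + 0.3 * x**2 - 0.5 * y**2
    peak = np.max(np.abs(p))
    return p / peak if peak > 0 else p


def make_cardiac_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the three-compartment cardiac phantom from its configuration."""
    cfg = config or PhantomConfig()
    grid = GridSpec(cfg.grid_shape, cfg.fov_mm)
    half_fov = np.asarray(cfg.fov_mm) / 2.0

    semi = np.asarray(cfg.heart_semiaxes_mm, dtype=float)
    center = np.asarray(cfg.heart_center_mm, dtype=float)
    if np.all(semi > 0):
        for d in range(3):
            if center[d] - semi[d] < -half_fov[d] or center[d] + semi[d] > half_fov[d]:
                raise ValueError(
                    f"heart spheroid exceeds the FOV along the {_AXES[d]} axis"
                )

    pts = grid.centers_mm()  # (n_vox, 3), x-fastest linearization
    x, y, z = pts.T

    body = (
        (x / cfg.body_semiaxes_mm[0]) ** 2
        + (y / cfg.body_semiaxes_mm[1]) ** 2
        + (z / cfg.body_semiaxes_mm[2]) ** 2
    ) <= 1.0

    labels = np.full(grid.n_voxels, OUTSIDE, dtype=int)
    labels[body] = OTHER

    # Chest wall: curved slab adjacent to the anterior (-y) FOV edge.
    y_front = (
        -half_fov[1]
        + cfg.chest_wall_standoff_mm
        + cfg.chest_wall_bow_mm
        * ((x / half_fov[0]) ** 2 + (z / half_fov[2]) ** 2)
    )
    chest = body & (y >= y_front) & (y < y_front + cfg.chest_wall_thickness_mm)
    labels[chest] = CHEST_WALL

    # Heart: spheroid (empty when any semi-axis is zero).
    if np.all(semi > 0):
        heart = (
            ((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2
        ) <= 1.0
        labels[heart & body] = HEART

    label_map = labels.reshape(grid.shape, order="F")
    if cfg.trim_heart_base_slices > 0:
        n = int(cfg.trim_heart_base_slices)
        tail = label_map[:, :, -n:]
        tail[tail == HEART] = OTHER
        label_map[:, :, -n:] = tail

    resonances = default_compartment_spectra()
    if cfg.spectra is not None:
        for name, lines in cfg.spectra.items():
            if name not in _COMPARTMENT_NAMES:
                raise ValueError(
                    f"unknown compartment name {name!r}; expected one of "
                    f"{sorted(_COMPARTMENT_NAMES)}"
                )
            resonances[_COMPARTMENT_NAMES[name]] = list(lines)
    if cfg.excitation_center_hz is not None and cfg.excitation_bandwidth_hz:
        resonances = {
            c: [_apply_excitation(r, cfg) for r in lines]
            for c, lines in resonances.items()
        }

    density = np.where(label_map >= 0, 1.0, 0.0)
    return Phantom(
        grid=grid,
        label_map=label_map,
        resonances=resonances,
        delta_f_map=cfg.b0_peak_hz * _smooth_poly(grid, 0),
        phase_map=cfg.phase_peak_rad * _smooth_poly(grid, 1),
        b1_tx_map=np.ones(grid.shape),
        density_map=density,
    )


def refine_phantom(phantom: Phantom, factor: int) -> Phantom:
    """Subdivide the phantom grid while keeping its piecewise-constant maps.

    Each fine voxel takes the labels/maps of the coarse voxel whose box
    contains its center (nearest coarse center), so the refined phantom is
    the same piecewise-constant object sampled more finely: simulated
    k-space data then converge to the continuous FT of the voxelized
    phantom.  ``factor`` must be odd so fine centers never fall on coarse
    box boundaries.
    """
    if factor < 1 or factor % 2 == 0:
        raise ValueError("refinement factor must be a positive odd integer")
    if factor == 1:
        return phantom
    grid = phantom.grid.oversampled(factor)
    # Nearest-coarse-center index per axis, periodic: fine centers beyond
    # the last coarse box wrap around, consistent with the DFT convention
    # where integer-k encoding is periodic over the FOV.
    idx = []
    for m, mf in zip(phantom.grid.shape, grid.shape):
        x = (np.arange(mf) - mf // 2) / mf
        j = np.round(x * m + m // 2).astype(int) % m
        idx.append(j)
    ix, iy, iz = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")

    def up(vol: np.ndarray) -> np.ndarray:
        return np.asarray(vol)[ix, iy, iz]

    return Phantom(
        grid=grid,
        label_map=up(phantom.label_map),
        resonances=phantom.resonances,
        delta_f_map=up(phantom.delta_f_map),
        phase_map=up(phantom.phase_map),
        b1_tx_map=up(phantom.b1_tx_map),
        density_map=up(phantom.density_map),
    )


def _apply_excitation(r: ResonanceParams, cfg: PhantomConfig) -> ResonanceParams:
    """Scale a resonance amplitude by a Gaussian excitation profile (FWHM =
    excitation bandwidth, centered at the excitation frequency)."""
    df = r.frequency_hz - float(cfg.excitation_center_hz)
    w = float(np.exp(-4.0 * np.log(2.0) * (df / cfg.excitation_bandwidth_hz) ** 2))
    return replace(r, amplitude=r.amplitude * w)


# ---------------------------------------------------------------------------
# Time-domain signal synthesis
# ---------------------------------------------------------------------------

def _compartment_base_fid(
    lines: list[ResonanceParams], t: np.ndarray
) -> np.ndarray:
    out = np.zeros(t.shape, dtype=complex)
    for r in lines:
        out += (
            r.amplitude
            * np.exp(1j * r.phase_rad)
            * np.exp((1j * 2.0 * np.pi * r.frequency_hz - np.pi * r.linewidth_hz) * t)
        )
    return out


def voxel_fid(
    phantom: Phantom,
    voxel_index: tuple[int, int, int],
    n_time: int,
    dwell_s: float,
) -> np.ndarray:
    """Time-domain signal of one voxel, sampled at t = n * dwell_s.

    The voxel signal is the sum over its compartment's resonances of
    ``a rho(x) B1(x) exp(i(phi_r + phi(x))) exp(i 2 pi (f_r + df(x)) t)
    exp(-pi lw_r t)``; voxels outside the body return zeros.
    """
    idx = tuple(int(i) for i in voxel_index)
    for i, (j, m) in enumerate(zip(idx, phantom.grid.shape)):
        if not 0 <= j < m:
            raise IndexError(f"voxel index {idx} out of range along {_AXES[i]}")
    t = np.arange(n_time) * float(dwell_s)
    label = int(phantom.label_map[idx])
    if label == OUTSIDE or label not in phantom.resonances:
        return np.zeros(n_time, dtype=complex)
    base = _compartment_base_fid(phantom.resonances[label], t)
    scale = (
        phantom.density_map[idx]
        * phantom.b1_tx_map[idx]
        * np.exp(1j * phantom.phase_map[idx])
    )
    return scale * base * np.exp(1j * 2.0 * np.pi * phantom.delta_f_map[idx] * t)


def all_voxel_fids(phantom: Phantom, n_time: int, dwell_s: float) -> np.ndarray:
    """FIDs of every voxel, shape (n_voxels, n_time), package linearization."""
    t = np.arange(n_time) * float(dwell_s)
    labels = ravel_map(phantom.label_map)
    dens = ravel_map(phantom.density_map)
    b1 = ravel_map(phantom.b1_tx_map)
    phase = ravel_map(phantom.phase_map)
    df = ravel_map(phantom.delta_f_map)
    out = np.zeros((labels.size, n_time), dtype=complex)
    for label, lines in phantom.resonances.items():
        sel = labels == label
        if not np.any(sel):
            continue
        base = _compartment_base_fid(lines, t)
        coef = dens[sel] * b1[sel] * np.exp(1j * phase[sel])
        shift = np.exp(1j * 2.0 * np.pi * np.outer(df[sel], t))
        out[sel] = coef[:, None] * shift * base[None, :]
    return out


# ---------------------------------------------------------------------------
# Phase-encoded acquisition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSpaceData:
    """Phase-encoded time-domain data; repeats stored summed, not averaged."""

    scheme: PhaseEncodeScheme
    data: np.ndarray  # complex, (n_channels, M', n_time)
    dwell_s: float
    noise_sd_per_average: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("data must have shape (n_channels, M', n_time)")
        if d.shape[1] != self.scheme.n_encodes:
            raise ValueError(
                f"data has {d.shape[1]} encodes but scheme has {self.scheme.n_encodes}"
            )
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be positive")
        if self.noise_sd_per_average < 0:
            raise ValueError("noise SD must be non-negative")
        object.__setattr__(self, "data", d.astype(complex))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]


def forward_encode(
    phantom: Phantom,
    scheme: PhaseEncodeScheme,
    sensitivity: np.ndarray | CoilGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_time: int = 256,
    dwell_s: float = 2.0e-4,
) -> KSpaceData:
    """Simulate the phase-encoded multi-channel acquisition of a phantom.

    ``sensitivity`` may be a per-channel per-voxel map of shape
    (n_channels, n_voxels), a :class:`CoilGeometry` (converted through the
    Biot-Savart model and normalized to unit mean over the body), or None
    for a single uniform channel.  Noise is drawn independently per repeat,
    channel, encode and time point as circular complex Gaussian noise with
    complex standard deviation ``noise_sd`` per average, then summed over
    the R_m repeats of each encode.  Runs with the same seed are
    bit-reproducible.
    """
    if tuple(scheme.fov_mm) != tuple(phantom.grid.fov_mm):
        raise ValueError(
            f"scheme FOV {scheme.fov_mm} does not match phantom FOV {phantom.grid.fov_mm}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    sens = _as_sensitivity(sensitivity, phantom)
    n_channels = sens.shape[0]

    fids = all_voxel_fids(phantom, n_time, dwell_s)  # (n_vox, N)
    centers = phantom.grid.centers_normalized()  # (n_vox, 3)
    encode = np.exp(-2j * np.pi * (scheme.k_coords @ centers.T))  # (M', n_vox)
    weighted = scheme.repeats[:, None] * encode

    data = np.empty((n_channels, scheme.n_encodes, n_time), dtype=complex)
    for ch in range(n_channels):
        data[ch] = weighted @ (sens[ch][:, None] * fids)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total = scheme.total_readouts()
        offsets = np.concatenate(([0], np.cumsum(scheme.repeats)[:-1]))
        scale = noise_sd / np.sqrt(2.0)
        for ch in range(n_channels):
            draws = scale * (
                rng.standard_normal((total, n_time))
                + 1j * rng.standard_normal((total, n_time))
            )
            data[ch] += np.add.reduceat(draws, offsets, axis=0)

    return KSpaceData(scheme=scheme, data=data, dwell_s=float(dwell_s), noise_sd_per_average=float(noise_sd))


def _as_sensitivity(
    sensitivity: np.ndarray | CoilGeometry | None, phantom: Phantom
) -> np.ndarray:
    n_vox = phantom.grid.n_voxels
    if sensitivity is None:
        return np.ones((1, n_vox))
    if isinstance(sensitivity, CoilGeometry):
        maps = biot_savart_sensitivity(sensitivity, phantom.grid)
        body = ravel_map(phantom.label_map) >= 0
        norm = maps[:, body].mean() if np.any(body) else maps.mean()
        return maps / norm if norm > 0 else maps
    sens = np.asarray(sensitivity)
    if sens.ndim == 1:
        sens = sens[None, :]
    if sens.shape[1] != n_vox:
        raise ValueError(f"sensitivity has {sens.shape[1]} voxels, expected {n_vox}")
    return sens
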