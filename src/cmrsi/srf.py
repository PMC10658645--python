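"""Spatial response functions (SRF) and Fourier voxel point-spread functions.

The SRF beta_c(x) of a compartment operator gives the complex weight
with which signal at every FOV position contributes to that
compartment's reconstructed spectrum:
``beta_c(x) = sum_m h_cm R_m exp(-i 2 pi k_m . x~)``.
Its magnitude is the worst-case contamination bound (realized when the
local B0-induced phase exactly opposes the SRF phase) and can further
be weighted by the receive sensitivity to estimate likely in-practice
contamination.  The FT-MRS analogue for a single voxel is the PSF of
the (possibly acquisition-weighted) scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .encoding import PhaseEncodeScheme
from .grids import GridSpec, ravel_map, unravel_map
from .recon import CompartmentMask, ReconOperator

__all__ = [
    "SRFMap",
    "compute_srf",
    "worst_case_srf",
    "b1_weighted_srf",
    "ft_psf",
    "psf_contour_mask",
    "leakage_report",
    "upsample_labels",
]


@dataclass(frozen=True)
class SRFMap:
    """A (possibly magnitude / sensitivity-weighted) SRF on an eval grid."""

    compartment_id: int | None
    values: np.ndarray  # complex or real, eval-grid shaped
    grid: GridSpec
    kind: str = "srf"  # "srf" | "worst_case" | "b1_weighted" | "psf"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != eval grid {self.grid.shape}")
        object.__setattr__(self, "values", v)


def _eval_positions(grid: GridSpec) -> np.ndarray:
    return grid.centers_normalized()


def compute_srf(
    op: ReconOperator,
    eval_grid: GridSpec | None = None,
    oversample: int = 1,
) -> list[SRFMap]:
    """SRFs of every compartment of an operator on an evaluation grid.

    The default evaluation grid is the operator's mask grid; pass
    ``oversample`` > 1 (or an explicit grid) for smooth display and
    leakage quadrature.
    """
    if op.scheme is None:
        raise ValueError("operator carries no scheme; SRF evaluation needs k-coordinates")
    grid = eval_grid if eval_grid is not None else op.mask.grid.oversampled(oversample)
    pos = _eval_positions(grid)
    n_enc = op.scheme.n_encodes
    beta = np.empty((op.pseudoinverse.shape[0], pos.shape[0]), dtype=complex)
    # evaluate in position blocks to bound the (M' x P) basis memory
    block = max(1, (1 << 22) // max(n_enc, 1))
    for lo in range(0, pos.shape[0], block):
        hi = min(lo + block, pos.shape[0])
        basis = op.scheme.repeats[:, None] * np.exp(
            -2j * np.pi * (op.scheme.k_coords @ pos[lo:hi].T)
        )
        beta[:, lo:hi] = op.pseudoinverse @ basis
    return [
        SRFMap(
            compartment_id=c,
            values=unravel_map(beta[i], grid.shape),
            grid=grid,
            kind="srf",
        )
        for i, c in enumerate(op.mask.compartment_ids)
    ]


def worst_case_srf(srf: SRFMap) -> SRFMap:
    """Magnitude SRF: the worst-case spectral-contamination bound."""
    return replace(srf, values=np.abs(srf.values), kind="worst_case")


def b1_weighted_srf(srf: SRFMap, sensitivity: np.ndarray) -> SRFMap:
    """Weight a magnitude SRF pointwise by a receive-sensitivity map.

    The sensitivity map is used as given; zero it near the coil (see the
    Biot-Savart exclusion radius) before calling if required.
    """
    sens = np.asarray(sensitivity)
    if sens.ndim == 1:
        sens = unravel_map(sens, srf.grid.shape)
    if sens.shape != srf.grid.shape:
        raise ValueError(f"sensitivity shape {sens.shape} != eval grid {srf.grid.shape}")
    mag = np.abs(srf.values) if np.iscomplexobj(srf.values) else srf.values
    return replace(srf, values=mag * sens, kind="b1_weighted")


def ft_psf(
    scheme: PhaseEncodeScheme,
    voxel: tuple[int, int, int],
    eval_grid: GridSpec | None = None,
    oversample: int = 1,
) -> SRFMap:
    """Point spread function of one FT-MRS voxel, normalized to unit max.

    ``psf(x) = sum_m R_m exp(-i 2 pi k_m . (x~ - x~_voxel))`` so the
    acquisition weights act as the apodizing window of the PSF.
    """
    base = GridSpec(scheme.matrix_shape, scheme.fov_mm)
    grid = eval_grid if eval_grid is not None else base.oversampled(oversample)
    center = np.array(
        [(int(voxel[d]) - base.shape[d] // 2) / base.shape[d] for d in range(3)]
    )
    pos = _eval_positions(grid) - center[None, :]
    psf = scheme.repeats @ np.exp(-2j * np.pi * (scheme.k_coords @ pos.T))
    peak = np.abs(psf).max()
    if peak > 0:
        psf = psf / peak
    return SRFMap(compartment_id=None, values=unravel_map(psf, grid.shape), grid=grid, kind="psf")


def psf_contour_mask(psf: SRFMap, threshold: float = 0.64) -> np.ndarray:
    """Boolean iso-contour mask where |PSF| >= threshold * max |PSF|."""
    mag = np.abs(psf.values)
    return mag >= threshold * mag.max()


def upsample_labels(label_map: np.ndarray, factor: int) -> np.ndarray:
    """Box-consistent upsampling of a label volume by an integer factor.

    Every fine voxel takes the label of the coarse voxel whose box
    ``[c_j - w/2, c_j + w/2)`` contains its center under the package
    coordinate convention (with periodic wrap at the FOV edge, matching
    the integer-k DFT encoding), so quadrature over an upsampled
    compartment integrates the correct region.
    """
    lab = np.asarray(label_map)
    idx = []
    for m in lab.shape:
        mf = m * factor
        x = (np.arange(mf) - mf // 2) / mf
        idx.append(np.floor(m * x + m // 2 + 0.5).astype(int) % m)
    ix, iy, iz = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    return lab[ix, iy, iz]


def leakage_report(
    srfs: list[SRFMap],
    mask: CompartmentMask,
    sensitivity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Worst-case leakage integrals per (source region, target compartment).

    Each entry is the integral (sum times evaluation-cell volume in
    FOV-normalized units) of the worst-case (optionally
    sensitivity-weighted) SRF magnitude of the target compartment over the
    source region.  Diagonal entries quantify in-compartment weight; the
    off-diagonal entries bound intercompartment contamination.
    """
    if not srfs:
        raise ValueError("no SRF maps given")
    grid = srfs[0].grid
    factors = [g // m for g, m in zip(grid.shape, mask.label_map.shape)]
    if len(set(factors)) != 1 or factors[0] * mask.label_map.shape[0] != grid.shape[0]:
        raise ValueError("evaluation grid must be an integer oversampling of the mask grid")
    labels = ravel_map(upsample_labels(mask.label_map, factors[0]))
    cell_volume = float(np.prod([1.0 / n for n in grid.shape]))
    sens = None
    if sensitivity is not None:
        sens = np.asarray(sensitivity).ravel(order="F")
        if sens.size != labels.size:
            raise ValueError("sensitivity must live on the evaluation grid")
    rows = []
    for srf in srfs:
        mag = np.abs(ravel_map(srf.values))
        if sens is not None:
            mag = mag * sens
        for region in mask.compartment_ids:
            sel = labels == region
            rows.append(
                {
                    "target_compartment": srf.compartment_id,
                    "source_region": region,
                    "leakage": float(mag[sel].sum() * cell_volume),
                }
            )
    return pd.DataFrame(rows)
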