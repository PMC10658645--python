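"""File interfaces: NIfTI volumes, HDF5 k-space containers, CSV tables.

Volumes (label maps, field maps, SRFs) are written as NIfTI with a
diagonal affine carrying the voxel size in mm.  K-space data travel in
an HDF5 container with the phase-encode scheme table embedded, so a
file is self-describing.  Phase-encode schemes round-trip through CSV
losslessly at 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .encoding import PhaseEncodeScheme
from .grids import GridSpec
from .phantom import KSpaceData
from .recon import CompartmentMask, CompartmentSpectra, ReconOperator
from .srf import SRFMap

__all__ = [
    "save_volume_nifti",
    "load_volume_nifti",
    "save_kspace_h5",
    "load_kspace_h5",
    "save_spectra_csv",
    "load_yaml_config",
    "operator_cache_key",
    "save_operator",
    "load_operator",
    "save_srf_montage_png",
]


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    for d in range(3):
        aff[d, d] = grid.voxel_size_mm[d]
        aff[d, 3] = -grid.fov_mm[d] / 2.0
    return aff


def save_volume_nifti(path: str | Path, volume: np.ndarray, grid: GridSpec) -> None:
    import nibabel as nib

    vol = np.asarray(volume)
    if np.iscomplexobj(vol):  # store magnitude; complex NIfTI support is patchy
        vol = np.abs(vol)
    img = nib.Nifti1Image(vol.astype(np.float64), _affine(grid))
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    shape = data.shape[:3]
    fov = tuple(z * n for z, n in zip(zooms, shape))
    return data, GridSpec(tuple(shape), fov)


def save_kspace_h5(path: str | Path, kdata: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=kdata.data)
        f.attrs["dwell_s"] = kdata.dwell_s
        f.attrs["noise_sd_per_average"] = kdata.noise_sd_per_average
        sch = f.create_group("scheme")
        sch.create_dataset("k_coords", data=kdata.scheme.k_coords)
        sch.create_dataset("repeats", data=kdata.scheme.repeats)
        sch.attrs["fov_mm"] = kdata.scheme.fov_mm
        sch.attrs["matrix_shape"] = kdata.scheme.matrix_shape


def load_kspace_h5(path: str | Path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        scheme = PhaseEncodeScheme(
            k_coords=f["scheme/k_coords"][()],
            repeats=f["scheme/repeats"][()],
            fov_mm=tuple(f["scheme"].attrs["fov_mm"]),
            matrix_shape=tuple(int(v) for v in f["scheme"].attrs["matrix_shape"]),
        )
        return KSpaceData(
            scheme=scheme,
            data=f["data"][()],
            dwell_s=float(f.attrs["dwell_s"]),
            noise_sd_per_average=float(f.attrs["noise_sd_per_average"]),
        )


def save_spectra_csv(path: str | Path, spectra: CompartmentSpectra) -> None:
    import pandas as pd

    cols = {}
    for i, c in enumerate(spectra.compartment_ids):
        cols[f"comp{c}_time_real"] = spectra.time_signals[i].real
        cols[f"comp{c}_time_imag"] = spectra.time_signals[i].imag
        cols[f"comp{c}_spec_real"] = spectra.spectra[i].real
        cols[f"comp{c}_spec_imag"] = spectra.spectra[i].imag
    df = pd.DataFrame(cols)
    df.insert(0, "frequency_hz", spectra.frequency_axis_hz())
    df.to_csv(path, index=False)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


# -- operator disk cache ----------------------------------------------------

def operator_cache_key(scheme: PhaseEncodeScheme, mask: CompartmentMask, kind: str) -> str:
    h = hashlib.sha256()
    h.update(kind.encode())
    h.update(np.ascontiguousarray(scheme.k_coords).tobytes())
    h.update(np.ascontiguousarray(scheme.repeats).tobytes())
    h.update(json.dumps([scheme.fov_mm, scheme.matrix_shape]).encode())
    h.update(np.ascontiguousarray(mask.label_map).tobytes())
    h.update(json.dumps(mask.compartment_ids).encode())
    return h.hexdigest()[:32]


def save_operator(cache_dir: str | Path, op: ReconOperator) -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = operator_cache_key(op.scheme, op.mask, op.kind)
    path = cache_dir / f"{op.kind.lower()}_{key}.npz"
    np.savez(
        path,
        encoding_matrix=op.encoding_matrix,
        pseudoinverse=op.pseudoinverse,
        compartment_sizes=op.compartment_sizes,
        condition_number=op.condition_number,
    )
    return path


def load_operator(
    cache_dir: str | Path,
    scheme: PhaseEncodeScheme,
    mask: CompartmentMask,
    kind: str,
) -> ReconOperator | None:
    key = operator_cache_key(scheme, mask, kind)
    path = Path(cache_dir) / f"{kind.lower()}_{key}.npz"
    if not path.exists():
        return None
    with np.load(path) as f:
        return ReconOperator(
            kind=kind,
            encoding_matrix=f["encoding_matrix"],
            pseudoinverse=f["pseudoinverse"],
            scheme=scheme,
            mask=mask,
            compartment_sizes=f["compartment_sizes"],
            condition_number=float(f["condition_number"]),
        )


def save_srf_montage_png(path: str | Path, srf: SRFMap, n_cols: int = 4) -> None:
    """Axial-slice montage of an SRF as percent of its maximum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mag = np.abs(srf.values)
    peak = mag.max()
    pct = 100.0 * mag / peak if peak > 0 else mag
    n_slices = pct.shape[2]
    n_rows = int(np.ceil(n_slices / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(2.2 * n_cols, 2.2 * n_rows))
    axes = np.atleast_1d(axes).ravel()
    for i in range(len(axes)):
        axes[i].axis("off")
        if i < n_slices:
            im = axes[i].imshow(pct[:, :, i].T, vmin=0, vmax=100, cmap="viridis")
            axes[i].set_title(f"slice {i}", fontsize=7)
    fig.colorbar(im, ax=axes.tolist(), shrink=0.7, label="% of max")
    fig.savefig(path, dpi=110)
    plt.close(fig)
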