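"""NIfTI / gradient-table / sidecar I/O.

DWI volumes travel as 4D NIfTI plus FSL-style plain-text tables (``.bval``:
one row of b-values; ``.bvec``: three rows of direction components).  SH
volumes are 4D NIfTI with the coefficient index on the 4th axis and a JSON
sidecar recording ``lmax``, basis convention, normalized flag and index
order.  Peak fields are stored zero-padded as a direction volume
(x, y, z, 15 = 5 peaks x 3 components) and an amplitude volume (x, y, z, 5).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .metrics import PeakSet
from .phantom import DWIVolume, GradientScheme

__all__ = [
    "read_scheme", "write_scheme", "read_dwi", "write_dwi",
    "read_sh", "write_sh", "write_peaks", "read_peaks",
    "peaks_to_arrays", "arrays_to_peaks", "write_labels", "read_labels",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def write_scheme(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_scheme(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got shape {bvecs.shape}")
    if bvecs.shape[1] != len(bvals):
        raise ValueError("bval/bvec volume counts disagree")
    return GradientScheme(bvals, bvecs.T)


def write_dwi(dwi: DWIVolume, nii_path, bval_path=None, bvec_path=None) -> None:
    nii_path = Path(nii_path)
    nib.save(nib.Nifti1Image(dwi.signal, _affine(dwi.voxel_size)), nii_path)
    stem = str(nii_path).removesuffix(".gz").removesuffix(".nii")
    write_scheme(dwi.scheme, bval_path or stem + ".bval", bvec_path or stem + ".bvec")


def read_dwi(nii_path, bval_path=None, bvec_path=None) -> DWIVolume:
    nii_path = Path(nii_path)
    img = nib.load(nii_path)
    stem = str(nii_path).removesuffix(".gz").removesuffix(".nii")
    scheme = read_scheme(bval_path or stem + ".bval", bvec_path or stem + ".bvec")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("DWI NIfTI must be 4D")
    if data.shape[3] != len(scheme.bvals):
        raise ValueError(
            f"volume count {data.shape[3]} does not match gradient table {len(scheme.bvals)}"
        )
    voxel = float(img.header.get_zooms()[0])
    return DWIVolume(data, scheme, voxel)


def write_sh(
    sh_vol: np.ndarray,
    path,
    voxel_size: float,
    lmax: int = 8,
    normalized: bool = False,
    convention: str = "descoteaux",
) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(sh_vol), _affine(voxel_size)), path)
    sidecar = {
        "lmax": lmax,
        "normalized": normalized,
        "convention": convention,
        "index_order": "l ascending even, m ascending",
    }
    Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_sh(path) -> tuple[np.ndarray, dict, float]:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(
        Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json").read_text()
    )
    return np.asarray(img.dataobj, dtype=float), meta, float(img.header.get_zooms()[0])


def peaks_to_arrays(peaks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Object array of PeakSets -> zero-padded (x,y,z,5,3) + (x,y,z,5)."""
    shape = peaks.shape
    dirs = np.zeros(shape + (5, 3))
    amps = np.zeros(shape + (5,))
    for idx in np.ndindex(shape):
        p = peaks[idx]
        n = len(p)
        if n:
            dirs[idx][:n] = p.directions[:5]
            amps[idx][:n] = p.amplitudes[:5]
    return dirs, amps


def arrays_to_peaks(dirs: np.ndarray, amps: np.ndarray) -> np.ndarray:
    out = np.empty(amps.shape[:3], dtype=object)
    for idx in np.ndindex(amps.shape[:3]):
        n = int((amps[idx] > 0).sum())
        out[idx] = PeakSet(dirs[idx][:n], amps[idx][:n], voxel=idx)
    return out


def write_peaks(peaks: np.ndarray, dirs_path, amps_path, voxel_size: float) -> None:
    dirs, amps = peaks_to_arrays(peaks)
    nib.save(nib.Nifti1Image(dirs.reshape(*dirs.shape[:3], 15), _affine(voxel_size)), dirs_path)
    nib.save(nib.Nifti1Image(amps, _affine(voxel_size)), amps_path)


def read_peaks(dirs_path, amps_path) -> np.ndarray:
    dirs = np.asarray(nib.load(dirs_path).dataobj, dtype=float)
    amps = np.asarray(nib.load(amps_path).dataobj, dtype=float)
    return arrays_to_peaks(dirs.reshape(*dirs.shape[:3], 5, 3), amps)


def write_labels(labels: np.ndarray, path, voxel_size: float) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(voxel_size)), path)


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj).astype(int)
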