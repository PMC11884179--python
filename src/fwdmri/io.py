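"""File formats: NIfTI volumes, FSL-dialect gradient tables, CSV tables.

Images are NIfTI-1 (2 mm isotropic header for generated phantoms);
gradients follow the FSL dialect (b-values on one whitespace-separated
row, gradient vectors as three rows of x, y, z components).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .synthetic import AcquisitionScheme, Phantom
from .roi import LabelAtlas

logger = logging.getLogger(__name__)


class DataError(Exception):
    """Input data malformed or inconsistent."""


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """FSL dialect: bvals one row; bvecs three rows (x, y, z)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise DataError(f"bvec file has shape {bvecs.shape}, expected 3 x N or N x 3")
    return bvals, bvecs


def load_dwi_dataset(
    nifti_path, bval_path, bvec_path, mask_path=None
) -> tuple[np.ndarray, np.ndarray, AcquisitionScheme, np.ndarray | None]:
    """Load and validate a DWI dataset.

    Checks the image is 4D with one volume per gradient entry, and
    renormalizes b > 0 gradient vectors to unit length (warning when the
    deviation exceeds 1e-3).

    Returns (dwi, affine, scheme, mask-or-None).
    """
    dwi, affine = load_nifti(nifti_path)
    if dwi.ndim != 4:
        raise DataError(f"expected a 4D image, got {dwi.ndim}D from {nifti_path}")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if len(bvals) != len(bvecs):
        raise DataError(
            f"bval has {len(bvals)} entries but bvec has {len(bvecs)}"
        )
    if dwi.shape[-1] != len(bvals):
        raise DataError(
            f"image has {dwi.shape[-1]} volumes but gradient table has {len(bvals)}"
        )
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        raise DataError("zero gradient vector at b > 0")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        logger.warning(
            "renormalizing %d gradient vectors deviating from unit norm by > 1e-3",
            int(np.sum(np.abs(norms - 1.0) > 1e-3)),
        )
    bvecs = bvecs.astype(float)
    bvecs[dw] = bvecs[dw] / norms[:, None]
    scheme = AcquisitionScheme(bvals=bvals, bvecs=bvecs)
    mask = None
    if mask_path is not None:
        mask_data, _ = load_nifti(mask_path)
        if mask_data.shape != dwi.shape[:-1]:
            raise DataError(
                f"mask shape {mask_data.shape} != image grid {dwi.shape[:-1]}"
            )
        mask = mask_data > 0
    return dwi, affine, scheme, mask


def save_phantom(phantom: Phantom, out_dir, prefix: str = "phantom") -> dict[str, Path]:
    """Write a phantom's DWI, gradients, labels, and ground-truth maps."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": save_nifti(phantom.dwi, phantom.affine, out_dir / f"{prefix}_dwi.nii.gz"),
        "labels": save_nifti(
            phantom.labels.astype(np.int32), phantom.affine,
            out_dir / f"{prefix}_labels.nii.gz",
        ),
        "f_true": save_nifti(phantom.f_true, phantom.affine, out_dir / f"{prefix}_ftrue.nii.gz"),
    }
    bval = out_dir / f"{prefix}.bval"
    bvec = out_dir / f"{prefix}.bvec"
    write_bvals_bvecs(phantom.scheme, bval, bvec)
    paths["bval"] = bval
    paths["bvec"] = bvec
    return paths


def save_atlas(atlas: LabelAtlas, affine: np.ndarray, out_dir, prefix: str = "atlas") -> dict[str, Path]:
    """Write WM/GM label volumes plus the JSON name/lobe sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wm": save_nifti(atlas.wm_labels, affine, out_dir / f"{prefix}_wm.nii.gz"),
        "gm": save_nifti(atlas.gm_labels, affine, out_dir / f"{prefix}_gm.nii.gz"),
    }
    sidecar = out_dir / f"{prefix}.json"
    atlas.save_sidecar(sidecar)
    paths["sidecar"] = sidecar
    return paths
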