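"""Conventional single-tensor reconstruction.

Log-linear least-squares fit of the diffusion tensor model

    S_i = S0 * exp(-b_i * g_i' D g_i)

to a diffusion-weighted volume, plus the scalar maps (FA, MD) derived
from the tensor eigenvalues.  Diffusivities are expressed in um^2/ms and
b-values internally in ms/um^2, so a b = 1000 s/mm^2 shell enters the
exponent as b = 1.0.

The single-tensor fit is both a deliverable (uncorrected FA/MD maps) and
the initializer for the bi-tensor free-water fit in :mod:`fwdmri.freewater`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Signals are floored at this value before taking logs so that zero or
# negative magnitudes from noise cannot produce -inf attenuations.
ATTENUATION_FLOOR = 1e-8

# Negative eigenvalues from noisy fits are clamped here for FA/MD only;
# the raw tensor is retained for diagnostics.
EIGENVALUE_FLOOR = 1e-6


class InvalidTensorError(ValueError):
    """Raised when a tensor violates symmetry or positive-definiteness."""


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with S0 and a validity mask.

    Attributes
    ----------
    tensors : ndarray, shape (..., 3, 3)
        Symmetric tensors in um^2/ms.
    s0 : ndarray, shape (...)
        Estimated non-diffusion-weighted signal.
    mask : ndarray of bool, shape (...)
        True where the fit is valid; masked-out voxels carry no tensor
        (their entries are zero).
    """

    tensors: np.ndarray
    s0: np.ndarray
    mask: np.ndarray


@dataclass
class ScalarMaps:
    """FA (unitless, in [0, 1]) and MD (um^2/ms) maps."""

    fa: np.ndarray
    md: np.ndarray


def design_matrix(scheme, with_s0: bool = True) -> np.ndarray:
    """Log-linear design matrix: ln S = X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].

    b-values are converted to ms/um^2 so the tensor coefficients come out
    in um^2/ms.
    """
    b = scheme.b_ms_um2
    g = scheme.bvecs
    quad = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    X = -b[:, None] * quad
    if with_s0:
        X = np.column_stack([np.ones(len(b)), X])
    return X


def tensor_from_components(comp: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3) symmetric."""
    out = np.empty(comp.shape[:-1] + (3, 3), dtype=comp.dtype)
    out[..., 0, 0] = comp[..., 0]
    out[..., 1, 1] = comp[..., 1]
    out[..., 2, 2] = comp[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = comp[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = comp[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = comp[..., 5]
    return out


def components_from_tensor(tensors: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tensor_from_components`."""
    return np.stack(
        [
            tensors[..., 0, 0],
            tensors[..., 1, 1],
            tensors[..., 2, 2],
            tensors[..., 0, 1],
            tensors[..., 0, 2],
            tensors[..., 1, 2],
        ],
        axis=-1,
    )


def fit_single_tensor(dwi: np.ndarray, scheme, mask: np.ndarray | None = None) -> TensorField:
    """Fit one diffusion tensor per voxel by log-linear least squares.

    Parameters
    ----------
    dwi : ndarray, shape (..., n_volumes)
        Diffusion-weighted signal; the last axis matches the scheme.
    scheme : AcquisitionScheme
        Must contain at least one b=0 volume and >= 6 distinct b>0
        directions (otherwise the 6 tensor degrees of freedom are not
        identifiable).
    mask : ndarray of bool, optional
        Voxels to fit; defaults to all.

    Voxels whose signal is entirely non-positive are marked invalid
    rather than aborting the fit.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != len(scheme):
        raise ValueError(
            f"dwi has {dwi.shape[-1]} volumes but scheme has {len(scheme)} entries"
        )
    if scheme.n_b0 < 1:
        raise ValueError("scheme must contain at least one b=0 volume")
    n_dirs = int(np.sum(~scheme.b0_mask))
    if n_dirs < 6:
        raise ValueError(f"need >= 6 diffusion-weighted directions, got {n_dirs}")

    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    valid = mask & np.any(dwi > 0, axis=-1)

    X = design_matrix(scheme)
    pinv = np.linalg.pinv(X)  # (7, n_volumes)

    sig = np.clip(dwi[valid], ATTENUATION_FLOOR, None)
    beta = np.log(sig) @ pinv.T  # (n_voxels, 7)

    tensors = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    tensors[valid] = tensor_from_components(beta[:, 1:])
    s0[valid] = np.exp(beta[:, 0])
    return TensorField(tensors=tensors, s0=s0, mask=valid)


def fa_md_from_eigenvalues(evals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD from eigenvalue arrays of shape (..., 3).

    FA = sqrt(3/2) * ||lam - mean||_2 / ||lam||_2, clipped to [0, 1];
    the all-zero tensor is assigned FA = 0.  Negative eigenvalues are
    clamped to a small positive floor first.
    """
    ev = np.clip(np.asarray(evals, dtype=float), EIGENVALUE_FLOOR, None)
    md = ev.mean(axis=-1)
    dev = ev - md[..., None]
    norm_sq = np.sum(ev**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum(dev**2, axis=-1) / norm_sq)
    fa = np.where(norm_sq > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md


def tensor_scalars(field: TensorField) -> ScalarMaps:
    """FA/MD maps of a tensor field; invalid voxels get FA = MD = 0."""
    evals = np.linalg.eigvalsh(field.tensors)
    fa, md = fa_md_from_eigenvalues(evals)
    fa = np.where(field.mask, fa, 0.0)
    md = np.where(field.mask, md, 0.0)
    return ScalarMaps(fa=fa, md=md)
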