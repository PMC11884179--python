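"""Single-shell bi-tensor free-water estimation.

Each voxel's signal is modelled as a mixture of an anisotropic tissue
compartment and an isotropic free-water compartment with fixed
diffusivity d:

    S_i = S0 * [(1 - f) * exp(-b_i g_i' D g_i) + f * exp(-b_i d)]

Fitting f and D jointly from a single shell is ill-posed, so the fit is
constrained the way the single-shell free-water literature prescribes:

* initialization of f from the single-tensor MD map against a reference
  tissue MD of 0.6 um^2/ms,
* tissue-tensor eigenvalues confined to [0.1, 2.5] um^2/ms,
* free-water diffusivity fixed at d = 3.0 um^2/ms (water at 37 C),
* voxels with single-tensor MD > 0.8 * d treated as CSF and excluded
  (assigned f = 1, no tissue tensor),
* a fixed budget of 100 refinement iterations.

Refinement is projected gradient descent on the data-fidelity objective
(plus an optional spatial-smoothness penalty on f), with Gauss-Newton
diagonal scaling and per-voxel backtracking so the objective never
increases.  Projection clips f to [0, 1] and the tensor eigenvalues to
the constraint box after every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dti
from .dti import ATTENUATION_FLOOR, TensorField, fa_md_from_eigenvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConstraints:
    """Biological constraints of the single-shell bi-tensor fit.

    Attributes
    ----------
    md_tissue : float
        Reference tissue mean diffusivity (um^2/ms) anchoring the f
        initialization.
    lambda_min, lambda_max : float
        Eigenvalue box (um^2/ms) for the corrected tissue tensor.
    d : float
        Free-water diffusivity (um^2/ms), water at body temperature.
    csf_md_factor : float
        Voxels with single-tensor MD strictly greater than
        ``csf_md_factor * d`` are excluded as CSF.
    n_iter : int
        Number of refinement iterations.
    step_size : float
        Initial relative step of the scaled gradient descent.
    alpha : float
        Spatial-regularization weight on ||grad f||^2 (0 = voxelwise fit).
    """

    md_tissue: float = 0.6
    lambda_min: float = 0.1
    lambda_max: float = 2.5
    d: float = 3.0
    csf_md_factor: float = 0.8
    n_iter: int = 100
    step_size: float = 1.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.lambda_min < self.md_tissue < self.lambda_max < self.d:
            raise ValueError(
                "constraints must satisfy 0 < lambda_min < md_tissue < "
                f"lambda_max < d, got {self}"
            )
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")

    @property
    def csf_md_threshold(self) -> float:
        return self.csf_md_factor * self.d


@dataclass
class FreeWaterFit:
    """Result of the bi-tensor fit.

    ``f`` is 1 and the tensor undefined in CSF-excluded voxels; fwcFA and
    fwcMD are NaN wherever no corrected tensor exists (never silently 0).
    """

    f: np.ndarray                 # free-water fraction, [0, 1]
    tensor: np.ndarray            # corrected tissue tensor (..., 3, 3)
    fwcfa: np.ndarray
    fwcmd: np.ndarray
    csf_mask: np.ndarray          # True where excluded by the MD rule
    fit_mask: np.ndarray          # True where the bi-tensor fit ran
    objective: np.ndarray = field(default_factory=lambda: np.array([]))
    n_step_halvings: int = 0


def initialize_free_water_map(
    md_map: np.ndarray, constraints: FitConstraints = FitConstraints(), b: float = 1.0
) -> np.ndarray:
    """Initial f from the single-tensor MD map.

    Interpolates the observed mono-exponential attenuation at b
    (ms/um^2) between the pure-tissue (MD = md_tissue -> f = 0) and
    pure-water (MD = d -> f = 1) endpoints:

        f0 = (exp(-b*MD_t) - exp(-b*MD_obs)) / (exp(-b*MD_t) - exp(-b*d))

    clipped to [0, 1].
    """
    e_t = np.exp(-b * constraints.md_tissue)
    e_w = np.exp(-b * constraints.d)
    f0 = (e_t - np.exp(-b * np.asarray(md_map, dtype=float))) / (e_t - e_w)
    return np.clip(f0, 0.0, 1.0)


def csf_exclusion_mask(
    md_map: np.ndarray, constraints: FitConstraints = FitConstraints()
) -> np.ndarray:
    """Voxels with MD strictly greater than 0.8*d, treated as CSF."""
    return np.asarray(md_map, dtype=float) > constraints.csf_md_threshold


def _project_eigenvalues(comp: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip eigenvalues of symmetric tensors (component form) into [lo, hi]."""
    tensors = dti.tensor_from_components(comp)
    evals, evecs = np.linalg.eigh(tensors)
    evals = np.clip(evals, lo, hi)
    proj = np.einsum("...ij,...j,...kj->...ik", evecs, evals, evecs)
    return dti.components_from_tensor(proj)


def initialize_tissue_tensor(
    atten: np.ndarray, scheme, f_init: np.ndarray, constraints: FitConstraints
) -> np.ndarray:
    """Initial tissue tensor (component form) given f.

    Subtracts the free-water compartment from the observed attenuations,
    renormalizes by (1 - f), and refits a tensor log-linearly; the result
    is projected into the eigenvalue box.  ``atten`` holds S/S0 for the
    b > 0 volumes only.
    """
    dw = ~scheme.b0_mask
    b = scheme.b_ms_um2[dw]
    e_iso = np.exp(-b * constraints.d)
    f = np.clip(f_init, 0.0, 0.99)[..., None]
    tissue = (atten - f * e_iso) / (1.0 - f)
    tissue = np.clip(tissue, ATTENUATION_FLOOR, 1.0)
    X = dti.design_matrix(scheme, with_s0=False)[dw]
    comp = np.log(tissue) @ np.linalg.pinv(X).T
    return _project_eigenvalues(comp, constraints.lambda_min, constraints.lambda_max)


def _model_attenuation(f, comp, G2, b, e_iso):
    q = comp @ G2.T
    a_t = np.exp(-b[None, :] * q)
    return (1.0 - f)[:, None] * a_t + f[:, None] * e_iso[None, :], a_t


def refine_bitensor_fit(
    dwi: np.ndarray,
    scheme,
    f_init: np.ndarray,
    tensor_init: np.ndarray,
    constraints: FitConstraints = FitConstraints(),
    mask: np.ndarray | None = None,
    s0: np.ndarray | None = None,
) -> FreeWaterFit:
    """Refine (f, D) by projected, scaled gradient descent.

    Minimizes, over the voxels in ``mask``,

        E = sum_v sum_i (S_hat_i(f_v, D_v) - S_i)^2 / S0_v^2
            + alpha * sum_v ||grad f||^2

    for ``constraints.n_iter`` iterations.  Gradients are scaled by the
    Gauss-Newton diagonal, and a per-voxel backtracking line search
    halves the step wherever a voxel's objective would increase, so the
    total objective is non-increasing.  After every step f is clipped to
    [0, 1] and the tensor eigenvalues to [lambda_min, lambda_max].

    Parameters
    ----------
    f_init, tensor_init
        Initialization maps on the full grid; ``tensor_init`` may be
        (..., 3, 3) tensors or (..., 6) components.
    mask
        Voxels to fit (CSF-excluded voxels should already be removed).
    s0
        Per-voxel S0; defaults to the mean over b=0 volumes.
    """
    dwi = np.asarray(dwi, dtype=float)
    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if s0 is None:
        s0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    mask = mask & (s0 > 0)

    dw = ~scheme.b0_mask
    b = scheme.b_ms_um2[dw]
    g = scheme.bvecs[dw]
    G2 = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )
    e_iso = np.exp(-b * constraints.d)

    atten = dwi[..., dw][mask] / s0[mask][:, None]  # (V, N)
    f = np.clip(np.asarray(f_init, dtype=float)[mask], 0.0, 1.0)
    tensor_init = np.asarray(tensor_init, dtype=float)
    if tensor_init.shape[-2:] == (3, 3):
        comp = dti.components_from_tensor(tensor_init)[mask]
    else:
        comp = tensor_init[mask].copy()
    comp = _project_eigenvalues(comp, constraints.lambda_min, constraints.lambda_max)

    use_smooth = constraints.alpha > 0
    alpha = constraints.alpha
    if use_smooth:
        # 6-neighbourhood edges between in-mask voxels, as indices into
        # the packed voxel vector; the smoothness term is
        # alpha * sum_edges (f_a - f_b)^2  (a discrete ||grad f||^2).
        vox_index = np.full(shape, -1, dtype=np.int64)
        vox_index[mask] = np.arange(int(mask.sum()))
        edge_a, edge_b = [], []
        for axis in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            a = vox_index[tuple(sl_lo)].ravel()
            bidx = vox_index[tuple(sl_hi)].ravel()
            keep = (a >= 0) & (bidx >= 0)
            edge_a.append(a[keep])
            edge_b.append(bidx[keep])
        edge_a = np.concatenate(edge_a)
        edge_b = np.concatenate(edge_b)
        degree = np.bincount(edge_a, minlength=int(mask.sum())) + np.bincount(
            edge_b, minlength=int(mask.sum())
        )

    def smooth_energy(f_flat):
        if not use_smooth:
            return 0.0
        return alpha * float(np.sum((f_flat[edge_a] - f_flat[edge_b]) ** 2))

    def smooth_half_gradient(f_flat):
        # (1/2) d/df of the smoothness term: alpha * (deg * f - sum of neighbours)
        neigh = np.bincount(edge_a, weights=f_flat[edge_b], minlength=f_flat.size)
        neigh += np.bincount(edge_b, weights=f_flat[edge_a], minlength=f_flat.size)
        return alpha * (degree * f_flat - neigh)

    A, a_t = _model_attenuation(f, comp, G2, b, e_iso)
    resid = A - atten
    e_vox = np.sum(resid**2, axis=1)
    trace = [float(e_vox.sum()) + (smooth_energy(f) if use_smooth else 0.0)]

    # Levenberg damping of the Gauss-Newton preconditioner: the damped
    # step interpolates between the full GN direction (fast near the
    # optimum of this shallow, ill-conditioned valley) and plain
    # gradient descent (safe far away); per-voxel backtracking raises
    # the damping wherever a step would increase the objective.
    damp = np.full(f.shape, 1e-2 / constraints.step_size)
    n_halvings = 0
    eye7 = np.eye(7)

    for _ in range(constraints.n_iter):
        df_model = e_iso[None, :] - a_t                       # dA/df
        dq = -(1.0 - f)[:, None] * b[None, :] * a_t           # dA/dq
        # Jacobian (V, N, 7): columns f, then the 6 tensor components
        J = np.empty(f.shape + (len(b), 7))
        J[:, :, 0] = df_model
        J[:, :, 1:] = dq[:, :, None] * G2[None, :, :]
        JtJ = np.einsum("vni,vnj->vij", J, J)
        g = np.einsum("vni,vn->vi", J, resid)                 # (1/2) grad of data term
        if use_smooth:
            g[:, 0] += smooth_half_gradient(f)
            JtJ[:, 0, 0] += alpha * degree

        if use_smooth:
            # neighbour sums at the current iterate, for the local
            # (frozen-neighbour) smoothness change used in the accept test
            nb = np.bincount(edge_a, weights=f[edge_b], minlength=f.size)
            nb += np.bincount(edge_b, weights=f[edge_a], minlength=f.size)

        active = np.ones(f.shape, dtype=bool)
        f_new, comp_new = f.copy(), comp.copy()
        e_new, a_t_new, resid_new = e_vox.copy(), a_t.copy(), resid.copy()
        for _try in range(8):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            M = JtJ[idx] + (damp[idx, None, None] + 1e-10) * eye7[None]
            try:
                delta = np.linalg.solve(M, -g[idx][..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.einsum(
                    "vij,vj->vi", np.linalg.pinv(M), -g[idx]
                )
            f_c = np.clip(f[idx] + delta[:, 0], 0.0, 1.0)
            comp_c = _project_eigenvalues(
                comp[idx] + delta[:, 1:], constraints.lambda_min, constraints.lambda_max
            )
            A_c, a_t_c = _model_attenuation(f_c, comp_c, G2, b, e_iso)
            r_c = A_c - atten[idx]
            e_c = np.sum(r_c**2, axis=1)
            if use_smooth:
                ds = alpha * (
                    degree[idx] * (f_c**2 - f[idx] ** 2)
                    - 2.0 * nb[idx] * (f_c - f[idx])
                )
                ok = e_c + ds <= e_vox[idx] + 1e-12
            else:
                ok = e_c <= e_vox[idx] + 1e-12
            good, bad = idx[ok], idx[~ok]
            f_new[good] = f_c[ok]
            comp_new[good] = comp_c[ok]
            e_new[good] = e_c[ok]
            a_t_new[good] = a_t_c[ok]
            resid_new[good] = r_c[ok]
            damp[good] = np.maximum(damp[good] * 0.3, 1e-8)
            damp[bad] *= 8.0
            n_halvings += int(bad.size)
            active[:] = False
            active[bad] = True

        if use_smooth:
            # couple through the smoothness term with a global accept test
            total_new = float(e_new.sum()) + smooth_energy(f_new)
            if total_new > trace[-1] + 1e-12:
                damp *= 8.0
                n_halvings += 1
                trace.append(trace[-1])
                continue
        f, comp, e_vox, a_t, resid = f_new, comp_new, e_new, a_t_new, resid_new
        trace.append(float(e_vox.sum()) + (smooth_energy(f) if use_smooth else 0.0))

    if n_halvings:
        logger.debug("step size halved %d times during refinement", n_halvings)

    f_map = np.full(shape, np.nan)
    f_map[mask] = f
    tensor_map = np.zeros(shape + (3, 3))
    tensor_map[mask] = dti.tensor_from_components(comp)
    evals = np.linalg.eigvalsh(tensor_map[mask])
    fa, md = fa_md_from_eigenvalues(evals)
    fwcfa = np.full(shape, np.nan)
    fwcmd = np.full(shape, np.nan)
    fwcfa[mask] = fa
    fwcmd[mask] = md
    return FreeWaterFit(
        f=f_map,
        tensor=tensor_map,
        fwcfa=fwcfa,
        fwcmd=fwcmd,
        csf_mask=np.zeros(shape, dtype=bool),
        fit_mask=mask,
        objective=np.asarray(trace),
        n_step_halvings=n_halvings,
    )


def free_water_corrected_scalars(fit: FreeWaterFit) -> dti.ScalarMaps:
    """fwcFA / fwcMD maps of the corrected tensor; excluded voxels are NaN."""
    evals = np.linalg.eigvalsh(fit.tensor[fit.fit_mask])
    fa, md = fa_md_from_eigenvalues(evals)
    fwcfa = np.full(fit.f.shape, np.nan)
    fwcmd = np.full(fit.f.shape, np.nan)
    fwcfa[fit.fit_mask] = fa
    fwcmd[fit.fit_mask] = md
    return dti.ScalarMaps(fa=fwcfa, md=fwcmd)


def fit_free_water(
    dwi: np.ndarray,
    scheme,
    mask: np.ndarray | None = None,
    constraints: FitConstraints = FitConstraints(),
) -> tuple[FreeWaterFit, TensorField, dti.ScalarMaps]:
    """Full free-water chain: single-tensor fit, CSF exclusion, init, refine.

    Returns the free-water fit plus the single-tensor field and its
    FA/MD maps (the uncorrected deliverables).
    """
    st = dti.fit_single_tensor(dwi, scheme, mask=mask)
    scalars = dti.tensor_scalars(st)
    csf = csf_exclusion_mask(scalars.md, constraints) & st.mask
    fit_mask = st.mask & ~csf

    f0 = initialize_free_water_map(scalars.md, constraints)
    s0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    dw = ~scheme.b0_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        atten = np.where(
            (s0 > 0)[..., None], dwi[..., dw] / np.where(s0 > 0, s0, 1.0)[..., None], 1.0
        )
    atten = np.clip(atten, ATTENUATION_FLOOR, 1.0)
    comp0 = initialize_tissue_tensor(atten, scheme, f0, constraints)

    fit = refine_bitensor_fit(
        dwi, scheme, f0, comp0, constraints=constraints, mask=fit_mask, s0=s0
    )
    # CSF voxels: f = 1, no corrected tensor
    fit.csf_mask = csf
    fit.f[csf] = 1.0
    fit.fwcfa[csf] = np.nan
    fit.fwcmd[csf] = np.nan
    return fit, st, scalars
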