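"""Synthetic data: DWI phantoms with known ground truth and cohort tables.

Two generators back the test and acceptance machinery:

* voxelwise bi-tensor phantoms — each voxel mixes an anisotropic tissue
  tensor with an isotropic free-water compartment of fixed diffusivity,
  optionally corrupted with Rician (magnitude) noise — so the single- and
  bi-tensor fitting stages can be checked against known truth;

* cohort ROI tables that emulate the statistical structure of a
  two-group (autism vs. neurotypical) aging study: the control group
  carries a linear age-related free-water increase (and fwcFA decrease)
  across ROIs, while the autism group has no age association but a mean
  free-water offset restricted to a designated subset of frontal tracts.

Units: diffusivities in um^2/ms, b-values stored in s/mm^2 and converted
to ms/um^2 inside the signal model (1000 s/mm^2 == 1.0 ms/um^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import roi as roi_mod
from .roi import FRONTAL_OFFSET_TRACTS, METRICS, ROI_NAMES, LabelAtlas, metric_columns

#: free-water diffusivity of water at body temperature, um^2/ms
FREE_WATER_DIFFUSIVITY = 3.0

#: header voxel size (mm) of generated phantoms, matching the acquisition
VOXEL_SIZE_MM = 2.0

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class InsufficientDirectionsError(ValueError):
    """Fewer than 6 distinct gradient directions: tensor not identifiable."""


# ---------------------------------------------------------------------------
# Acquisition scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm^2) and unit gradient directions of a DWI measurement."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (len(bvals), 3):
            raise ValueError(
                f"bvals length {bvals.shape} and bvecs shape {bvecs.shape} mismatch"
            )
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient vectors for b > 0 must have unit norm")
        if not np.any(~dw):
            raise ValueError("scheme must contain at least one b=0 entry")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in ms/um^2 (s/mm^2 divided by 1000)."""
        return self.bvals / 1000.0


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n well-spread unit vectors on the upper hemisphere (golden spiral).

    Diffusion measurements are antipodally symmetric, so spreading points
    over one hemisphere spreads them over the projective sphere.
    """
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    phi = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def make_acquisition_scheme(
    n_b0: int = 5, n_dirs: int = 64, b: float = 1000.0, seed: int = 0
) -> AcquisitionScheme:
    """Single-shell scheme: ``n_b0`` b=0 entries then ``n_dirs`` directions.

    Directions are a golden-spiral hemisphere set rotated by a seeded
    random rotation, giving a deterministic, approximately uniform scheme
    with a good tensor-design condition number.  Requires ``n_dirs >= 6``
    for the 6 tensor degrees of freedom.
    """
    if n_dirs < 6:
        raise InsufficientDirectionsError(
            f"n_dirs={n_dirs}: at least 6 directions needed to identify a tensor"
        )
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    rng = np.random.default_rng(seed)
    dirs = fibonacci_hemisphere(n_dirs) @ _random_rotation(rng).T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# Bi-tensor forward model and Rician noise
# ---------------------------------------------------------------------------

def simulate_voxel_signal(
    f: float,
    D: np.ndarray,
    s0: float,
    scheme: AcquisitionScheme,
    d: float = FREE_WATER_DIFFUSIVITY,
) -> np.ndarray:
    """Noiseless bi-tensor signal for one voxel.

        S_i = S0 * [(1 - f) * exp(-b_i g_i' D g_i) + f * exp(-b_i d)]

    with f the free-water volume fraction, D the tissue tensor (um^2/ms,
    symmetric positive-definite) and d the free-water diffusivity.
    b=0 entries return exactly S0.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"free-water fraction f={f} outside [0, 1]")
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("D must be a symmetric 3x3 tensor")
    if np.linalg.eigvalsh(D)[0] <= 0:
        raise ValueError("D must be positive-definite")
    b = scheme.b_ms_um2
    q = np.einsum("ij,jk,ik->i", scheme.bvecs, D, scheme.bvecs)
    return s0 * ((1.0 - f) * np.exp(-b * q) + f * np.exp(-b * d))


def add_rician_noise(
    signals: np.ndarray, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, signals.shape)
    e2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def tensor_from_eigen(
    eigenvalues: Sequence[float], principal_axis: Sequence[float] = (1.0, 0.0, 0.0)
) -> np.ndarray:
    """Symmetric tensor with given eigenvalues, first one along ``principal_axis``."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape != (3,) or np.any(ev <= 0):
        raise ValueError("eigenvalues must be 3 positive numbers")
    e1 = np.asarray(principal_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(ev) @ R.T


@dataclass(frozen=True)
class PhantomRegion:
    """Homogeneous phantom region: one tissue tensor and one f value."""

    name: str
    f: float
    eigenvalues: tuple[float, float, float] = (1.5, 0.3, 0.3)
    principal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    slab: tuple[int, int] | None = None  # [start, stop) along the z axis

    def tensor(self) -> np.ndarray:
        return tensor_from_eigen(self.eigenvalues, self.principal_axis)

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f_true={self.f} outside [0, 1]")
        if any(ev <= 0 for ev in self.eigenvalues):
            raise ValueError("eigenvalues must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid, regions, signal level and noise of a synthetic DWI phantom.

    ``snr = None`` means noiseless; otherwise Rician noise with
    ``sigma = s0 / snr`` is applied.  Regions either all carry explicit
    z-axis slabs (which must tile the grid without overlap) or are
    auto-assigned equal contiguous blocks of voxels.
    """

    grid_shape: tuple[int, int, int]
    regions: tuple[PhantomRegion, ...]
    s0: float = 1.0
    snr: float | None = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("SNR must be positive (or None for noiseless)")
        if not self.regions:
            raise ValueError("need at least one region")
        if len({r.name for r in self.regions}) != len(self.regions):
            raise ValueError("duplicate region names")


@dataclass
class Phantom:
    """A simulated DWI dataset with its ground truth."""

    dwi: np.ndarray            # (x, y, z, n_volumes)
    labels: np.ndarray         # (x, y, z) int, regions 1..R
    region_names: tuple[str, ...]
    f_true: np.ndarray         # (x, y, z)
    tensor_true: np.ndarray    # (x, y, z, 3, 3)
    affine: np.ndarray
    scheme: AcquisitionScheme


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    slabs = [r.slab for r in spec.regions]
    if any(s is not None for s in slabs):
        if any(s is None for s in slabs):
            raise ValueError("either all regions carry slabs or none do")
        labels = np.zeros(shape, dtype=np.int32)
        covered = np.zeros(shape[2], dtype=bool)
        for i, (start, stop) in enumerate(slabs):
            if covered[start:stop].any():
                raise ValueError(f"overlapping region slabs at z=[{start},{stop})")
            covered[start:stop] = True
            labels[:, :, start:stop] = i + 1
        if not covered.all():
            raise ValueError("region slabs do not tile the grid")
        return labels
    n_vox = int(np.prod(shape))
    if n_vox < len(spec.regions):
        raise ValueError("fewer voxels than regions")
    flat = np.zeros(n_vox, dtype=np.int32)
    for i, chunk in enumerate(np.array_split(np.arange(n_vox), len(spec.regions))):
        flat[chunk] = i + 1
    return flat.reshape(shape)


def build_phantom(spec: PhantomSpec, scheme: AcquisitionScheme) -> Phantom:
    """Simulate a 4D DWI volume region by region, with ground-truth maps.

    The affine encodes the 2 mm isotropic voxel size of the emulated
    acquisition.  b=0 volumes equal S0 exactly before noise.
    """
    labels = _region_labels(spec)
    shape = spec.grid_shape
    dwi = np.zeros(shape + (len(scheme),))
    f_true = np.zeros(shape)
    tensor_true = np.zeros(shape + (3, 3))
    for i, region in enumerate(spec.regions):
        sel = labels == i + 1
        signal = simulate_voxel_signal(region.f, region.tensor(), spec.s0, scheme)
        dwi[sel] = signal
        f_true[sel] = region.f
        tensor_true[sel] = region.tensor()
    if spec.snr is not None:
        sigma = spec.s0 / spec.snr
        dwi = add_rician_noise(dwi, sigma, seed=spec.seed)
    affine = np.diag([VOXEL_SIZE_MM, VOXEL_SIZE_MM, VOXEL_SIZE_MM, 1.0])
    return Phantom(
        dwi=dwi,
        labels=labels,
        region_names=tuple(r.name for r in spec.regions),
        f_true=f_true,
        tensor_true=tensor_true,
        affine=affine,
        scheme=scheme,
    )


def atlas_phantom_spec(
    grid_shape: tuple[int, int, int] = (16, 16, 8),
    snr: float | None = 30.0,
    seed: int = 0,
) -> PhantomSpec:
    """64-region phantom emulating the 32 WM tract + 32 GM ROI layout.

    WM regions get anisotropic tensors with seeded orientations and
    moderate free water; GM regions get weakly anisotropic tensors with
    somewhat higher free water.
    """
    rng = np.random.default_rng(seed)
    regions = []
    for name in ROI_NAMES:
        axis = rng.standard_normal(3)
        regions.append(
            PhantomRegion(
                name=f"wm_{name}",
                f=float(rng.uniform(0.1, 0.3)),
                eigenvalues=(1.5, 0.3, 0.3),
                principal_axis=tuple(axis / np.linalg.norm(axis)),
            )
        )
    for name in ROI_NAMES:
        axis = rng.standard_normal(3)
        regions.append(
            PhantomRegion(
                name=f"gm_{name}",
                f=float(rng.uniform(0.15, 0.35)),
                eigenvalues=(1.0, 0.65, 0.65),
                principal_axis=tuple(axis / np.linalg.norm(axis)),
            )
        )
    return PhantomSpec(grid_shape=grid_shape, regions=tuple(regions),
                       s0=1.0, snr=snr, seed=seed)


def phantom_atlas(phantom: Phantom) -> LabelAtlas:
    """Split a 64-region phantom's labels into WM and GM atlas volumes."""
    n = len(ROI_NAMES)
    if len(phantom.region_names) != 2 * n:
        raise ValueError(
            f"atlas mode needs {2 * n} regions (32 WM + 32 GM), "
            f"got {len(phantom.region_names)}"
        )
    wm = np.where((phantom.labels >= 1) & (phantom.labels <= n), phantom.labels, 0)
    gm = np.where(phantom.labels > n, phantom.labels - n, 0)
    return LabelAtlas(wm_labels=wm.astype(np.int32), gm_labels=gm.astype(np.int32))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: per-metric baseline values by tissue — plausible adult levels
_BASELINES: Mapping[str, Mapping[str, float]] = {
    "fw":    {"wm": 0.15, "gm": 0.22},
    "fwcfa": {"wm": 0.55, "gm": 0.25},
    "fwcmd": {"wm": 0.65, "gm": 0.75},
    "fa":    {"wm": 0.48, "gm": 0.20},
    "md":    {"wm": 0.78, "gm": 0.90},
}


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of the simulated two-group aging cohort.

    Controls (NT) carry linear age slopes: free water rises and fwcFA
    falls with age across ROIs (uncorrected FA falls and MD rises,
    mirroring the partial-volume effect); the autism group (ASD) has no
    age association but a constant free-water offset in
    ``offset_rois`` (white-matter tracts).  All metric columns get
    independent Gaussian residual noise.
    """

    n_per_group: int = 43
    age_range: tuple[float, float] = (30.0, 73.0)
    nt_fw_slope: float = 0.002        # fraction / year, all ROIs
    nt_fwcfa_slope: float = -0.002    # / year, WM tracts
    nt_fa_slope: float = -0.002       # / year, WM tracts (uncorrected)
    nt_md_slope: float = 0.002        # um^2/ms / year, all ROIs (uncorrected)
    asd_fw_offset: float = 0.03       # fraction, in offset_rois (WM)
    offset_rois: tuple[str, ...] = FRONTAL_OFFSET_TRACTS
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.01 for m in METRICS}
    )
    sex_p_male: float = 0.5
    trait_fw_beta: float = 0.0        # trait ~ baseline + beta * mean offset-tract fw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("need n >= 3 per group")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age range must be nondegenerate")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be positive")
        unknown = [r for r in self.offset_rois if r not in ROI_NAMES]
        if unknown:
            raise ValueError(f"unknown ROI names in offset subset: {unknown}")


def _metric_slope(spec: CohortSpec, metric: str, tissue: str) -> float:
    if metric == "fw":
        return spec.nt_fw_slope
    if metric == "fwcfa" and tissue == "wm":
        return spec.nt_fwcfa_slope
    if metric == "fa" and tissue == "wm":
        return spec.nt_fa_slope
    if metric == "md":
        return spec.nt_md_slope
    return 0.0


def simulate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the subjects x (covariates + 320 metric columns) table.

    Metric value = baseline + slope_NT * (age - age_mid)  [NT only]
                 + offset [ASD, fw, designated WM tracts] + N(0, sd),

    with age_mid the midpoint of the age range, so both groups share the
    same expected mean and between-group differences are confined to the
    offset tracts (age-associated change in controls and a frontal
    free-water group offset are separate effects, as in the emulated
    study design).

    ASD subjects additionally get an 'ados' trait score column (NaN for
    NT); by default the trait is independent of the imaging metrics.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    lo, hi = spec.age_range
    rows = []
    cols = metric_columns()
    for gi, group in enumerate(("ASD", "NT")):
        ages = rng.uniform(lo, hi, n)
        sexes = np.where(rng.random(n) < spec.sex_p_male, "M", "F")
        for k in range(n):
            row: dict = {
                "subject_id": f"{group.lower()}{k + 1:03d}",
                "group": group,
                "age_years": float(ages[k]),
                "sex": str(sexes[k]),
            }
            for col in cols:
                metric, tissue, roi_name = roi_mod.parse_variable(col)
                value = _BASELINES[metric][tissue]
                if group == "NT":
                    value += _metric_slope(spec, metric, tissue) * (
                        ages[k] - 0.5 * (lo + hi)
                    )
                elif metric == "fw" and tissue == "wm" and roi_name in spec.offset_rois:
                    value += spec.asd_fw_offset
                value += rng.normal(0.0, spec.noise_sd[metric])
                row[col] = value
            if group == "ASD":
                fw_cols = [f"fw_wm_{r}" for r in spec.offset_rois]
                mean_fw = float(np.mean([row[c] for c in fw_cols])) if fw_cols else 0.0
                row["ados"] = float(
                    max(0.0, 10.7 + spec.trait_fw_beta * mean_fw + rng.normal(0.0, 3.3))
                )
            else:
                row["ados"] = np.nan
            rows.append(row)
    return roi_mod.assemble_variable_table(rows)
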