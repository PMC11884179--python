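# Methods

## Signal model

Each voxel's diffusion-weighted signal is modelled as a two-compartment
mixture

    S_i = S0 [ (1 − f) exp(−b_i gᵢᵀ D gᵢ) + f exp(−b_i d) ],

an anisotropic tissue tensor `D` plus an isotropic free-water
compartment with fixed diffusivity `d`. Diffusivities are expressed in
μm²/ms and b-values in ms/μm², so the nominal b = 1000 s/mm² shell
enters the exponent as b = 1.0 and all exponents are dimensionless.
`d` is set to 3.0 μm²/ms, the diffusivity of free water at 37 °C.
(Printed values of this constant sometimes carry a stray 10⁻³ from
mm²/s conventions; 3.0 μm²/ms is the only value consistent with tissue
eigenvalue bounds quoted in μm²/ms, and is what this package uses.)

The assumptions inherited from the model: exactly two compartments, no
exchange, Gaussian diffusion in each, a single fixed isotropic
diffusivity for free water, and magnitude (Rician) noise.

## Fitting pipeline

1. **Single-tensor fit** (`fwdmri.dti`). Log-linear least squares of
   `ln S` on the tensor design matrix, jointly estimating `ln S0` and
   the six tensor components. Signals are floored at 1e-8 before the
   log; voxels with all-non-positive signal are flagged invalid rather
   than aborting. FA/MD come from the eigenvalues, with negative noisy
   eigenvalues clamped to 1e-6 for the scalar maps only. The log-linear
   (unweighted) variant was chosen for determinism and speed; at the
   SNRs considered the difference from weighted fits is far below the
   tolerances used anywhere in this package.

2. **CSF exclusion**. Voxels whose single-tensor MD exceeds
   0.8·d = 2.4 μm²/ms are treated as cerebrospinal fluid: they are
   assigned f = 1, receive no tissue tensor, and are NaN in the
   corrected maps. The inequality is strict ("greater than"), so
   MD = 2.4 is retained.

3. **Initialization**. The free-water fraction starts from the
   single-tensor MD map by log-interpolating the mono-exponential
   attenuation between a tissue reference MD_t = 0.6 μm²/ms (f = 0) and
   d (f = 1), clipped to [0, 1]. The tissue tensor is initialized by
   subtracting the implied free-water signal, renormalizing by (1 − f),
   and refitting a tensor log-linearly.

4. **Constrained refinement** (`fwdmri.freewater`). 100 iterations of
   projected descent on

       E = Σ_v Σ_i (Ŝ_i(f_v, D_v) − S_i)² / S0_v²  +  α Σ_edges (f_a − f_b)²,

   the data fidelity on attenuations plus (optionally, α > 0) a
   nearest-neighbour quadratic smoothness penalty on f. After every
   step f is clipped to [0, 1] and the tissue eigenvalues are projected
   onto [λ_min, λ_max] = [0.1, 2.5] μm²/ms, which also guarantees
   symmetry and positive-definiteness — a Cholesky or log
   parameterization of the tensor would add curvature without adding
   anything the eigenvalue projection does not already enforce.

   The descent direction is the Levenberg-damped Gauss–Newton step (a
   preconditioned gradient step): the single-shell (f, D) objective has
   an extremely shallow, ill-conditioned valley coupling f with the
   tensor trace, in which an unpreconditioned (or diagonally scaled)
   gradient step makes almost no progress within a 100-iteration
   budget, leaving f essentially at its initialization. With the damped
   Gauss–Newton direction the noiseless fit converges to machine
   precision well within the budget. Per-voxel backtracking (raising
   the damping wherever a voxel's objective would increase, eight
   inner retries) keeps the total objective monotonically
   non-increasing — the fit records the full objective trace and the
   number of damping events.

### Voxelwise vs regularized mode

The default is α = 0 (voxelwise): deterministic per voxel and directly
checkable against brute-force oracles. On noiseless data this recovers
f and the tissue tensor exactly.

On noisy single-shell data the voxelwise maximum-likelihood estimate is
unreliable *by construction* — the problem is ill-posed, and at SNR 30
roughly 40% of voxels collapse into a spurious f = 0 solution, giving a
bimodal estimate with mean absolute error ≈ 0.19 on phantoms. This is
precisely the failure mode spatial regularization exists to cure. The
regularized mode couples neighbouring f values through the quadratic
edge penalty; the smoothness term enters the accept test locally
(frozen-neighbour approximation) with a global monotonicity safety
net. On two-compartment phantoms at SNR 30 the mean absolute error in
f drops to ≈ 0.085 and is insensitive to the weight across
α ∈ [0.1, 3.0]; the default regularized weight is **α = 0.3**, chosen
from that phantom calibration. Noisy data should be fitted with the
regularized mode; oracle comparisons and noiseless analyses use α = 0.

## Synthetic data

`fwdmri.synthetic` provides the two generators every test builds on.

**Phantoms.** Regions with known (f, D) tile a 3D grid (2 mm isotropic
header); signals follow the forward model above, optionally with Rician
noise `sqrt((S + ε₁)² + ε₂²)`, ε ~ N(0, σ²), σ = S0/SNR. The default
SNR of 30 is a repository choice of a typical 3 T single-shell
acquisition, not a measured value. Gradient schemes are golden-spiral
hemisphere point sets under a seeded random rotation — deterministic,
well-conditioned, and approximately uniform on the projective sphere.
The 64-region "atlas" phantom mimics the 32 white-matter tract + 32
gray-matter ROI layout with seeded orientations.

**Cohorts.** The cohort generator emulates the statistical structure of
a two-group (ASD vs NT, 43 per group, ages 30–73) aging study directly
at the ROI-table level:

    value = baseline(metric, tissue)
          + slope_NT(metric, tissue) · (age − 51.5)   [NT only]
          + offset                                    [ASD, fw, 7 frontal tracts]
          + N(0, sd_metric)

Controls gain free water (+0.002/yr, all 64 ROIs) and lose fwcFA
(−0.002/yr, white matter) with age; uncorrected FA/MD carry matching
partial-volume-style slopes; the autism group has no age association
but a +0.03 free-water offset in seven designated frontal tracts (GR,
mOG, OC, PMd, PMv, preSMA, SMA). The age term is centered at the
age-range midpoint so the two groups share the same expected mean and
between-group differences are confined to the offset tracts. Residual
noise (sd 0.01 per metric) is independent Gaussian per column; an
"ados" trait score is generated for the ASD group, independent of the
imaging metrics unless a coupling is requested.

What the generator deliberately does **not** model: cross-ROI
correlation, scanner artifacts (eddy currents, motion, Gibbs ringing),
registration error, non-Gaussian residuals, and any nonlinearity in the
age trends. Passing tests therefore demonstrate that the estimators and
inference machinery recover the structure they target under clean
conditions — not that they are robust to the full messiness of scanner
data.

## Statistics

All permutation tests use the Freedman–Lane scheme: fit the reduced
(covariate-only) model, permute its residuals, add them back to the
reduced fit, and recompute the full-model statistic, giving
`p = (1 + #{|t*| ≥ |t|}) / (1 + N)`. P-values are two-sided; with N = 0
the statistic reduces to the parametric one. Permutation streams are
seeded per (variable, group) from the master seed, so full-table runs
are reproducible and order-independent.

* **Group differences**: ANCOVA `metric ~ group + age + sex`, t of the
  group contrast, 5000 permutations by default.
* **Age associations**: partial correlation of metric and age given
  sex, run separately per group; r is the correlation of the
  residualized variables, β the residual-regression slope in metric
  units per year, R² = r². Permuted predictor residuals are
  re-residualized on the covariates before correlating.
* **Quadratic follow-up**: t of the age² term (age centered before
  squaring, to reduce collinearity) against the reduced model with the
  linear term.
* **FDR**: Benjamini–Hochberg within each metric × tissue family of 32
  variables (q < 0.05), via statsmodels; trait analyses form their own
  family (the subset of group-significant tracts, e.g. 7).
* **Demographics**: pooled-variance two-sample t from summary
  statistics (Welch behind a flag) and Pearson χ² without continuity
  correction, via scipy.
* **Dispersion summaries**: per-group, per-lobe (frontal 17, temporal
  3, parietal 6, occipital 6) mean ± SE of R² and β, plus between-group
  mean differences. R² is unsigned; the sign of r is recorded
  alongside, since a signed goodness-of-fit display can be read either
  way.

Degenerate inputs are handled explicitly: a response fully explained by
the covariates yields t = 0, p = 1; zero residual variance raises; an
ROI with no valid voxels is reported missing, never zero; missing cells
are propagated and dropped listwise per analysis, not imputed.

## Problem sizes

The bundled tests and the acceptance script run at desk scale, chosen
as the smallest sizes at which each property is cleanly measurable:
phantom grids of 20×20×10 voxels (recovery) down to 4×4×2 (limits),
cohorts of 43 per group matching the emulated design, 1000 permutations
per test (the default remains 5000), and 1280 null variables for
type-I calibration. Cohort-level findings that depend on a specific
human sample are reproduced qualitatively (pattern and counts), not
numerically.

## Known limitations

* Single-shell free-water estimation remains ill-posed; the constraints
  and regularization make it usable, but f estimates in regions whose
  true tissue MD deviates from the 0.6 μm²/ms reference are biased (the
  initialization maps tissue MD ≠ MD_t onto nonzero f, and at low SNR
  part of that bias survives refinement). Estimates are therefore more
  reliable in white matter than gray matter.
* Exact equivalence with gradient-flow implementations of the
  variational framework is out of scope; the fit is validated by
  parameter recovery against ground truth and brute-force oracles.
* Only f is spatially regularized, not the tensor field.
* The statistics layer tests each variable marginally; covariance
  between ROIs is neither modelled nor exploited.
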