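# fwdmri

Single-shell free-water diffusion MRI analysis: constrained bi-tensor
fitting, free-water-corrected scalar maps, atlas-ROI aggregation, and
permutation-based group/age statistics — with synthetic phantom and
cohort generators so the whole pipeline is testable end to end without
access to scanner data.

## The problem

In diffusion MRI, voxels near cerebrospinal fluid mix signal from tissue
with signal from freely diffusing extracellular water. Conventional
single-tensor metrics (FA, MD) are biased by this partial-volume
contamination: MD is inflated and FA suppressed wherever free water
accumulates — which it does with age and in several clinical conditions.
The bi-tensor ("free water") model separates the two compartments:

    S_i = S0 [ (1 − f) exp(−b_i gᵢᵀ D gᵢ) + f exp(−b_i d) ]

where `f` is the voxel's free-water volume fraction, `D` the tissue
diffusion tensor, `d = 3.0 μm²/ms` the fixed diffusivity of water at
body temperature, and `(b_i, g_i)` the acquisition's b-values and
gradient directions (single shell: 5 × b=0 plus 64 × b=1000 s/mm²). FA
and MD of the corrected tensor `D` are the free-water-corrected metrics
fwcFA and fwcMD.

Estimating `(f, D)` from one shell is ill-posed, so the fit is
constrained: `f` is initialized from the single-tensor MD map against a
tissue reference MD of 0.6 μm²/ms, tissue eigenvalues are confined to
[0.1, 2.5] μm²/ms, voxels with MD > 0.8·d are excluded as CSF, and the
estimates are refined for 100 projected descent iterations (optionally
with a spatial smoothness penalty on `f`). See `docs/methods.md` for the
full model and numerical details.

Downstream, voxel maps are averaged over an atlas of 32 transcallosal
white-matter tracts and 32 homotopic gray-matter regions (5 metrics ×
64 ROIs = 320 variables per subject), and group differences / age
associations are tested with Freedman–Lane permutation ANCOVA and
permutation partial correlations, FDR-corrected within each
metric × tissue family.

## Worked example

Fit one noiseless voxel with 40% free water over a tissue tensor with
eigenvalues (1.5, 0.3, 0.3) μm²/ms (true tissue MD 0.7, FA 0.77):

```python
import numpy as np
from fwdmri import fit_free_water, make_acquisition_scheme, simulate_voxel_signal
from fwdmri.synthetic import tensor_from_eigen

scheme = make_acquisition_scheme(n_b0=5, n_dirs=64, b=1000.0, seed=1)
D_tissue = tensor_from_eigen((1.5, 0.3, 0.3))          # um^2/ms, MD = 0.7
signal = simulate_voxel_signal(f=0.4, D=D_tissue, s0=1.0, scheme=scheme)

fit, tensors, scalars = fit_free_water(signal[None, :], scheme)
print(f"single-tensor   FA = {scalars.fa[0]:.3f}   MD = {scalars.md[0]:.3f} um^2/ms")
print(f"free-water fit  f  = {fit.f[0]:.3f}  fwcFA = {fit.fwcfa[0]:.3f}  "
      f"fwcMD = {fit.fwcmd[0]:.3f} um^2/ms")
```

```
single-tensor   FA = 0.512   MD = 1.142 um^2/ms
free-water fit  f  = 0.400  fwcFA = 0.770  fwcMD = 0.700 um^2/ms
```

The single-tensor fit sees the contaminated voxel as low-FA, high-MD
tissue; the bi-tensor fit recovers the true free-water fraction and the
uncontaminated tissue metrics.

A full synthetic cohort run — 43 subjects per group, controls with an
age-related free-water increase, the autism group with a free-water
offset in seven designated frontal tracts — through permutation ANCOVA
and per-group age partial correlations (1000 permutations):

```python
from fwdmri import PipelineConfig, run_pipeline
from fwdmri.stats import PermutationPlan

config = PipelineConfig(
    out_dir="out", mode="cohort_table", seed=7,
    plan=PermutationPlan(n_permutations=1000, seed=7),
)
bundle = run_pipeline(config)

ancova = bundle.results["ancova"]
sig = ancova[ancova.q_flag == True]
print(f"{len(sig)} FDR-significant group differences "
      f"(all in family {set(sig.family)}):")
print(sorted(sig.variable))
age = bundle.results["age_partial"]
for g in ("NT", "ASD"):
    fam = age[(age.family == "fw_wm") & (age.group == g)]
    print(f"{g}: {int((fam.q_flag == True).sum())}/{len(fam)} tracts with "
          f"FDR-significant age-free-water correlation")
```

prints:

```
7 FDR-significant group differences (all in family {'fw_wm'}):
['fw_wm_GR', 'fw_wm_OC', 'fw_wm_PMd', 'fw_wm_PMv', 'fw_wm_SMA', 'fw_wm_mOG', 'fw_wm_preSMA']
NT: 32/32 tracts with FDR-significant age-free-water correlation
ASD: 0/32 tracts with FDR-significant age-free-water correlation
```

i.e. the analysis recovers exactly the seven planted frontal tracts as
group differences and the control-only age association. Each run writes
`table.csv` (subjects × 320 variables), per-analysis result CSVs, a
dispersion summary of R² and β by lobe, a plain-text report, and a JSON
manifest with seeds and constraint values.

The same stages are available from the shell:

```
fwdmri simulate-phantom --out-dir out --shape 16 16 8 --snr 30 --seed 1
fwdmri fit-fw --dwi out/phantom_dwi.nii.gz --bval out/phantom.bval \
              --bvec out/phantom.bvec --out-prefix out/sub01
fwdmri run-all --mode cohort_table --seed 7 --out-dir out
```

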