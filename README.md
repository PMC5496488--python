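# naadiff

Diffusion-weighted MR spectroscopy (DW-MRS) analysis of the intra-axonal
metabolite N-acetylaspartate (NAA): from cardiac-gated diffusion-weighted
PRESS transients of a white-matter voxel, plus a DTI scan of the same
region, to a per-voxel cytosolic NAA diffusivity and the longitudinal group
statistics built on it.

## Why

NAA is almost exclusively intraneuronal, so its diffusion reports on the
intra-axonal space specifically — unlike water DTI, which mixes axonal,
myelin, glial and extracellular compartments. In diseases with ongoing
axonal degeneration (the motivating application is multiple sclerosis, with
the corpus callosum as the target tract), a falling cytosolic NAA
diffusivity is a candidate marker of axonal injury that water diffusivity
cannot isolate. The catch is that the raw per-direction signal decay also
depends on where the spectroscopy voxel sits on the tract, how the tract
curves through it, and how dispersed the axons are — nuisances this package
models away.

## The model

For each diffusion condition (gradient direction g, b-value b), the NAA
attenuation is modeled as diffusion in zero-radius sticks dispersed about
the local fiber axis:

    E(b, g) = sum_v w_v * E_u [ exp( -b * D_cytosol * 1e-3 * (u . g)^2 ) ]

where v runs over the VOI voxels, the per-voxel mean axis (and hence its
angle theta_v to g) comes from the DTI primary eigenvector, and the stick
axis u deviates from that mean axis by a Gaussian polar angle with standard
deviation sigma_phi (uniform azimuth, antipodal axes identified). The two
free parameters — D_cytosol (um^2/ms) and sigma_phi (degrees) — are fitted
simultaneously to both gradient directions' NAA amplitudes, with the overall
scale S0 profiled out analytically and amplitudes weighted by their inverse
CRLB-derived variance. Macroscopic tract curvature is carried by the DTI
angles; microscopic orientation dispersion by sigma_phi; D_cytosol is then a
geometry-free property of the axoplasm.

Upstream of the fit the package implements the full processing chain:
per-transient zero-order phase and frequency-drift correction from the
residual water line, eddy-current correction against the unsuppressed water
reference, averaging, HSVD water removal, time-domain singlet fitting with
Cramer-Rao lower bounds, and a CRLB < 15% quality filter. Downstream, the
cohort statistics module provides six-month difference values, one-sample
t-tests, mixed-effects group comparisons (random subject intercepts, with
VOI-within-subject nesting), OLS associations and Mann-Whitney tests. A
synthetic-data subpackage generates DW-MRS scans, DWI tract volumes, and
longitudinal cohorts with known ground truth so that every stage is testable
without any acquisition.

## Worked example

Simulate one study-sized scan (8 diffusion conditions, 48 transients each
plus extra blocks at the strongest gradients, study-like SNR, ground truth
D_cytosol = 0.50 um^2/ms, sigma_phi = 18 deg) and run the full chain:

```bash
naadiff pipeline run --seed 7 --out demo
```

prints

```
simulated dataset written to demo/dataset
pipeline finished: D_cytosol = 0.4975 um^2/ms (sigma_phi = 18.51 deg)
```

`demo/result.json` carries the diagnostics behind those two numbers: the
fitted D_cytosol 0.4975 +- 0.0431 um^2/ms (uncertainty propagated from the
per-condition amplitude CRLBs, here 2.7-8.6%) brackets the simulated truth;
sigma_phi 18.5 +- 3.6 deg likewise. The model-free per-direction apparent
diffusion coefficients are 0.453 um^2/ms parallel and 0.019 um^2/ms
perpendicular to the fibers — the parallel ADC sits below D_cytosol because
orientation dispersion and tract curvature bleed signal attenuation out of
the parallel direction, which is exactly what the two-parameter model
corrects for.

The stages are also exposed individually (`naadiff simulate`, `preprocess`,
`quantify`, `dti`, `fit`, `stats`); chaining them by hand reproduces the
`pipeline run` result. `naadiff stats` takes a cohort table (TSV with one
row per subject/VOI/timepoint) and emits group summaries, six-month
difference tests, and mixed-effects comparisons with unadjusted p-values.

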