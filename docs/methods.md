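# Methods

`naadiff` estimates the cytosolic (intra-axonal) diffusivity of
N-acetylaspartate (NAA) in a coherent white-matter tract from
diffusion-weighted MR spectroscopy (DW-MRS), and the longitudinal group
statistics built on it. This note documents the models, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Signal model and acquisition

One scan acquires, for each diffusion condition (gradient direction g in the
VOI frame, b-value in s/mm^2), a set of single-shot complex FIDs from a PRESS
voxel on the corpus callosum, cardiac-gated, with de-optimized water
suppression so a residual water line remains usable for corrections. The
default protocol is the 3 T corpus-callosum scheme: TE 110 ms, 1024 points at
1500 Hz, bipolar diffusion gradients (delta 22 ms, Delta 55 ms, 20 ms gap),
directions [1,0,0] (fiber-parallel) with b = 290/890/1750/2860 and
[0,-1,1]/sqrt(2) (fiber-perpendicular) with b = 650/1760/3460/5730, 48
transients per condition plus an extra 48 at the strongest gradient of each
direction, and one unsuppressed on-resonance water reference per condition.

Unit conventions, fixed package-wide: diffusivities in um^2/ms, b-values in
s/mm^2, attenuation exponent `b * D * 1e-3`; frequencies in Hz relative to
the carrier on the NAA singlet (2.0 ppm), with
`ppm = 2.0 + f_Hz / 127.74 MHz` at 3 T, putting water (4.7 ppm) at +345 Hz.

## Preprocessing

Fixed order: per-transient zero-order phase and frequency correction ->
eddy-current correction -> uniform averaging within condition -> HSVD water
removal. The order matters: the corrections are estimated from the residual
water line, and averaging before phasing would destroy the metabolite signal
under phase jitter.

**Phase/frequency estimation.** The residual water peak is located in a
+-60 Hz window around its nominal frequency on the magnitude spectrum of the
matched-apodized FID (apodization at the prior water linewidth of 9 Hz
suppresses late-time noise; real weights do not shift the line center or its
phase). Parabolic interpolation on a 4x zero-filled FFT seeds a Newton
refinement of the DTFT magnitude maximum, which is exact for a noiseless
on-peak line; the zero-order phase is the DTFT phase at that maximum. The
peak must exceed 5x the spectral noise level (estimated from the FID tail).
A floor of 3 would accept the maximum of pure noise almost surely across the
~300 search bins, so 5 is used; transients that fail are flagged and
excluded, never interpolated. At a water peak SNR of 50 the estimator
recovers injected errors to ~0.6 degrees / 0.06 Hz (1 SD).

**Eddy-current correction.** The metabolite FID is multiplied by
`exp(-i arg(water(t)))`; because the simulated (and physical) eddy phase is
common to both acquisitions, this inverts it exactly wherever the water
magnitude exceeds 5x its tail noise SD. Beyond the last reliable sample the
unwrapped phase is held constant rather than extrapolated. Because the eddy
phase perturbs the water line and thereby biases the first-pass
phase/frequency estimates, a second phase/frequency pass runs after eddy
correction; on noiseless data the two-pass chain removes injected
phase/frequency/eddy artifacts to <1e-9 relative.

**Averaging.** Arithmetic mean of the surviving transients of a condition;
the extra highest-b block is pooled with its condition under uniform weights
(the acquisition does not distinguish them). The spectral noise SD is
estimated from the last 10% of the averaged FID.

**HSVD water removal.** The averaged FID is modeled as damped complex
exponentials by the state-space Hankel SVD method (Hankel matrix L = N/2
rows, rank K = 25, shift-invariance least squares for the poles, linear least
squares for amplitudes). Components inside 4.7 +- 0.35 ppm are subtracted;
growing poles (|z| > 1, non-physical for an FID) are never reconstructed.
On a synthetic NAA + water FID this cuts water-band energy by >99% while
changing the NAA amplitude by <1%.

A deterministic residue of the water-peak estimator remains: the NAA tail
under the water line biases the zero-order phase by ~0.05 degrees, so the
cleaned FID matches the true NAA signal to ~1e-3 relative (not machine
precision) even without noise. This cross-talk is common-mode — it cancels
in the attenuation ratios across conditions — and is invisible to the
magnitude-based quantification.

## Quantification and quality control

Each cleaned FID is fitted in the time domain with a sum of damped complex
exponentials (amplitude, frequency, damping, phase per singlet) by
Levenberg-Marquardt least squares on the stacked real/imaginary samples; the
first point enters with weight 1 and no apodization is applied. This is a
deliberate simplification relative to basis-set linear-combination fitting:
the simulated signal content is Lorentzian singlets, for which the
exponential model is exact. Negative-amplitude solutions are folded into the
phase.

The amplitude uncertainty is the Cramer-Rao lower bound from the Fisher
information `Re(J^H J)/sigma^2` of the full model at the fit (analytic
Jacobian, noise SD per real/imag sample from the preprocessing tail
estimate), reported as a percentage of the amplitude. Conditions with
CRLB% >= 15 are rejected (strict inequality keeps 14.9, drops 15.0); if
fewer than two b-values survive in either direction the decay is flagged
unusable for diffusion modeling. At the default synthetic SNR the CRLB sits
at 3-10% across conditions, mirroring a good in vivo acquisition.

## DTI and fiber geometry

The diffusion tensor is fitted per voxel by weighted log-linear least squares
(`ln S = ln S0 - b g^T T g`, weights = squared signals, non-positive signals
excluded) and diagonalized. Scalars follow the standard definitions:
FA; MD = (l1+l2+l3)/3; parallel diffusivity l1; perpendicular diffusivity
(l2+l3)/2. Negative eigenvalues are clamped to zero and flagged. Eigenvector
sign is fixed (first nonzero component positive) and all fiber-gradient
angles are folded to [0, 90] degrees, since the axis is physically
unoriented.

The fiber geometry of a spectroscopy VOI is the set of per-voxel angles
between the primary eigenvector and each DW-MRS gradient direction (gradients
rotated from the VOI frame into the image frame by an orthonormal matrix,
identity by default), with uniform voxel weights unless a white-matter
probability map is supplied. All mask voxels contribute; no FA threshold is
applied by default.

## The dispersed-stick model

NAA is confined to the intra-axonal space, so its diffusion-weighted signal
is modeled as diffusion inside zero-radius sticks. For a voxel whose mean
fiber axis makes angle theta with gradient g, with the stick axis u deviating
from the mean axis by a Gaussian polar angle (SD sigma_phi, uniform azimuth,
antipodal axes identified):

    E(b) = E_u[ exp(-b * D_cytosol * 1e-3 * (u.g)^2) ]

The VOI-level prediction averages E over the mask voxels with the geometry
weights — macroscopic curvature is carried by the per-voxel DTI angles,
microscopic dispersion by the single sigma_phi. The dispersion expectation
inside each voxel (rather than dispersing a mean direction) keeps the two
scales separate. The exact parametric form of the dispersion model is this
package's reconstruction of a two-parameter angle-corrected intra-axonal
model; it is not a verbatim port of any specific prior implementation.

**Quadrature.** The polar integral uses Gauss-Hermite quadrature (exact for
the Gaussian weight), the azimuth a trapezoid rule (spectrally accurate for
the periodic integrand). The default 32 x 64 nodes keep the relative error
below ~3e-7 for sigma_phi <= 35 degrees and ~2e-5 at the 89-degree bound,
verified against a 128 x 256 reference; 16 x 32 nodes were measured at only
~1e-3 near 45 degrees and were rejected. An independent Monte-Carlo sampler
(`attenuation_monte_carlo`) serves as the oracle in tests and never shares
code with the quadrature.

**Fitting.** The two parameters (D_cytosol, sigma_phi) are fitted
simultaneously to both directions' amplitudes by minimizing the weighted SSE
with the scale S0 profiled out analytically (it enters linearly, preserving a
two-parameter nonlinear problem; one S0 is shared across directions since
both come from the same VOI and metabolite). Weights are inverse-variance:
`w = 1/(CRLB% * A)^2`, i.e. 1/SD^2 in amplitude units (configurable to
uniform). L-BFGS-B runs from a 4 x 3 multistart grid
(D in {0.2,0.4,0.6,0.8}, sigma_phi in {5,20,40} degrees) with bounds
D in (0, 1.5], sigma_phi in [0, 89); ties break by lowest SSE then lowest D.
A solution at a bound is flagged non-identifiable — single-direction data
produce exactly this D/sigma_phi ridge. Parameter uncertainty is propagated
from the amplitude CRLBs through the Gauss-Newton normal matrix at the
solution; at study-like SNR this predicts sigma_D ~ 0.045 um^2/ms, and
simulated recovery matches it (RMSE 0.044 over 100 replicates at mean
CRLB 5%).

**Empirical ADC.** As a model-free fallback, a per-direction weighted
log-linear fit `ln A = ln A0 - b * ADC * 1e-3` (log-domain weights
1/CRLB%^2) gives the apparent diffusion coefficient; directions with fewer
than two positive amplitudes are omitted.

## Cohort statistics

Longitudinal differences are `delta = month6 - month0` per VOI (positive =
increase), tested against zero by a one-sample t-test. Two-group comparisons
use a linear mixed model with a random intercept per subject — participants
contribute up to two VOIs — adding a nested VOI-within-subject intercept
when several timepoints per VOI are analyzed together; variance components
by REML, fixed-effect inference by Wald. REML/Wald are this package's
choices; the alternative (ML / likelihood ratio) is noted but not
implemented. If the optimizer fails the comparison downgrades to a
two-sample test on subject means, explicitly flagged. Sex enters as a
covariate for MS-versus-healthy comparisons. Associations use OLS with
slope, R^2 and two-sided p. Ordinal clinical scores use the Mann-Whitney U
test, exact by enumeration for tie-free samples of total size <= 12, normal
approximation with tie correction otherwise. No multiple-comparison
correction is applied anywhere; all reported p-values are unadjusted.
Skewness/kurtosis are reported but never gate an analysis. Healthy-volunteer
repeat scans (days apart, not months) are analyzed only as a reproducibility
reference. Calibration at the defaults: the one-sample t type-I rate is
0.05 +- 0.01 over 1000 simulated null cohorts, and the mixed model recovers
a 0.07 um^2/ms group gap in the six-month change to within a few percent on
study-sized cohorts.

## Synthetic data: what it emulates, and what it does not

The spectral generator produces Lorentzian singlets (NAA at 2.0 ppm, 7 Hz
linewidth) scaled by the dispersed-stick attenuation of a configurable
(D, sigma_phi) truth on a given fiber geometry, a residual water line, and
the artifact chain in order: attenuation -> per-transient phase jitter
(SD 10 degrees) -> linear frequency drift (0.006 Hz per transient, ~3 Hz
over a scan) -> eddy phase `A exp(-t/tau) sin(2 pi t / T_e)` (0.5 rad,
tau 60 ms, period 120 ms) shared with the water reference -> amplitude
jitter (2%, residual cardiac pulsation) -> complex Gaussian noise. The
noise default puts the post-averaging NAA CRLB in the 3-10% range of an
accepted in vivo acquisition. Artifact magnitudes are plausible settings,
not reconstructions — the study did not publish its noise or drift levels.

Not simulated: PRESS localization and J-coupling (only singlets),
macromolecule baselines, T1-saturation variability from cardiac-gated TR,
motion/outliers beyond the SNR-floor flag, Rician statistics in the spectral
domain (complex Gaussian noise is used; magnitude operations occur only
after fitting). Passing tests therefore demonstrate correctness of the
processing chain and estimators under this generative model, not robustness
to every in vivo failure mode.

The DWI generator builds a planar-arc tract (default 30-degree total bend,
eigenvalues 1.85/0.73/0.73 um^2/ms — healthy callosal white matter) with
Gaussian or Rician noise. The cohort generator draws hierarchically
(subject effect ~ Normal(group baseline, between-SD); observation = subject
effect + timepoint effect + within-noise) with the study's design: 6
stable / 13 active / 6 healthy subjects, two VOIs each with single-VOI and
dropout patterns matching the published counts (11/25 baseline VOIs, 10/22
longitudinal pairs, 10 healthy twice-scanned volumes), month-3 scans for 11
active cases. Group baseline means (0.45/0.50/0.52 um^2/ms) and six-month
changes (+0.03/-0.04/0) follow the published group statistics; the printed
group SD (~0.07) is split into between-subject 0.06 and within-subject
(VOI/replicate) 0.035, a choice consistent with the published
reproducibility but not uniquely determined by it.

## Degenerate inputs and tie-breaks

Unit-norm violations in stored gradient directions are normalized on read
with a warning; a declared condition without transients is a consistency
error. All-flagged conditions are dropped with a warning. Zero-variance
delta samples make the t-test degenerate (flagged, no p-value). Constant
predictors are regression errors. Negative amplitudes are excluded from
log-linear fits. HSVD on an all-zero FID returns no components; an empty
water band is the identity.

## Problem sizes used in the shipped checks

The acceptance script simulates at the full acquisition size (8 conditions,
48 transients each plus two extra 48-blocks; twelve such scans for the
quality-filter pass fraction), uses 1e6 Monte-Carlo samples per forward-model
grid point, 100 replicates for noisy recovery, and 1000/500 simulated
cohorts for the t-test calibration and mixed-model recovery. Unit tests use
reduced transient counts (6 per condition) where only exactness, not
statistics, is at stake.
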