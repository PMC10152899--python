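# Methods

`neurofluid` reimplements, as a tested library plus analysis drivers, a
multimodal quantification pipeline for cerebrospinal-fluid (CSF) physiology
and amyloid burden in older adults: choroid-plexus (ChP) perfusion from
pseudo-continuous arterial spin labelling (pCASL), net CSF flow through the
aqueduct of Sylvius from cardiac-gated phase-contrast MRI, amyloid burden
from dynamic ¹¹C-PiB PET (static SUVr and SRTM2 binding potential with
region-based voxel-wise partial-volume correction), parasagittal-dural (PSD)
volumetrics with landmark-plane subsegmentation, and a rank-correlation
cohort analysis. Because no human data are distributed, every input is
generated by the `synth` subpackage with known ground truth; the tests and
the acceptance script quantify how faithfully the quantification stages
recover that truth.

## ASL perfusion

The label/control difference is formed by *surround subtraction*: each
volume is compared with the mean of its two temporally adjacent
opposite-condition neighbours. An interior surround estimate cancels a
linear temporal drift exactly, which is the purpose of the scheme, so the
time average is taken over interior estimates only; with a single
control/label pair no interior volume exists and plain pairwise subtraction
is the documented fallback. (Averaging in single-neighbour end estimates
would re-introduce an O(drift) bias, which is why the ends are excluded.)

CBF follows the single-compartment consensus model,

CBF = 6000 · λ · ΔM · exp(PLD_slice/T1b) / (2 · α · T1b[s] · M0 · (1 − e^(−τ/T1b))),

in ml/100 g/min, with PLD_slice = PLD + slice·Δt_slice for 2-D multislice
readouts. Defaults: τ = 1800 ms, PLD = 2000 ms, λ = 0.9 ml/g, α = 0.85,
T1b = 1650 ms — the consensus values; all config-overridable. Background
suppression is folded into α. Voxels with non-positive M0 are mapped to NaN
(not zero) so ROI means are unbiased; ROI perfusion is the mean over the
mask's finite voxels.

## Phase-contrast CSF flow

Phase maps to through-plane velocity as v = VENC·φ/π (VENC default
12 cm/s). Flux is Σ_ROI v·A_voxel per cardiac phase; the stroke volume is
the flux waveform integrated over one cycle with uniform rectangular bins
(equivalent to trapezoidal integration for uniform periodic sampling), and
net flow = stroke volume × heart rate = mean flux × 60 — hence exactly
heart-rate invariant for a fixed waveform, and exactly invariant to dilating
the ROI into static tissue. Positive velocity is cranial-to-caudal, so
negative net flow is anterograde; a flag flips the convention.

Velocities past VENC alias by ±2·VENC. Unaliasing shifts any sample that
deviates from the per-phase ROI spatial median by more than VENC by one
2·VENC step toward the median, and raises if a shifted sample still deviates
by more than VENC (beyond the single-wrap regime). A median reference
presumes an unwrapped majority at each phase. Under plug flow that premise
fails — all flowing voxels wrap together — so the simulator also offers a
blunted parabolic profile (rim at half the peak velocity, flux preserved)
in which only the core wraps; wrapped-flow validations use that profile, and
plug flow remains the simulator default.

## PET quantification

**Frames.** The default dynamic schedule is 4×15, 8×30, 9×60, 2×180 and
10×300 s (70 min total). The static route averages the frames tiling the
50–70 min window (exactly the last four 300-s frames), takes 10% trimmed
means over the global amyloid mask and cerebellar grey matter (trim =
floor(0.10·n) from each tail — the common reading of "10% trimmed mean"),
and reports their ratio (SUVr). Dose/weight SUV normalisation is omitted:
it cancels in the ratio. SUVr is invariant to global rescaling of the image.

**SRTM.** The simplified reference tissue model is fitted with basis
functions: for each candidate k2a = θ the model
C_T ≈ R1·C_R + φ·[C_R ⊗ e^(−θt)] is linear; θ is picked on a logarithmic
grid (64 points, 0.006–0.6 min⁻¹, config-overridable) by residual sum of
squares and then polished by a bounded scalar search between the adjacent
grid points, so recovery is not limited by the ~7.6% grid spacing. A best θ
on the grid boundary is flagged, not hidden. Derived parameters: k2 = φ +
R1·θ, BP_ND = k2/θ − 1, k2′ = k2/R1. Note that BP_ND is not invariant to
scaling the target TAC alone (DVR = BP_ND+1 scales with it); it is invariant
to joint rescaling of target and reference.

**SRTM2.** Step 1 fits full SRTM per voxel; k2′ is fixed to the median of
per-voxel k2′ over voxels with step-1 BP_ND > 0.1 (the brain mask over which
the median is taken is an explicit input). Step 2 refits one scale per
candidate θ, C_T ≈ R1·[C_R + (k2′ − θ)·C_R ⊗ e^(−θt)], and reports BP_ND =
R1·k2′/θ − 1 — the form implied by k2 = R1·k2′ and θ = k2a. Voxels sharing
an identical TAC are fitted once and broadcast (exact on noiseless
phantoms).

**Numerics.** All convolutions are evaluated on a 0.1-s uniform grid with
the exact exponential-convolution recursion for piecewise-linear inputs,
then averaged over frames; frame mid-times are never used as point samples
because the short early frames make midpoint sampling biased. The reference
curve is reconstructed from its frame means by midpoint interpolation
followed by an iterative adjustment until the interpolant's own frame means
reproduce the measurements (noiseless recovery improves from ~3% to
~0.01% relative error with this step).

**Partial-volume correction.** The geometric transfer matrix W has entries
W_ij = mean over region i of the PSF-blurred indicator of region j (Gaussian
PSF by FWHM, background treated as a region, mass leaving the FOV modelled
by zero-padding, so rows sum to ≤ 1). Solving W·m = t for the observed
region means t is exact on noiseless piecewise-constant images for any PSF
width. The voxel-level (RBV/Yang) step corrects f → f·s/(PSF⊗s) with
s(x) = m_label(x); voxels where the blurred synthetic image is below ε pass
through uncorrected and are counted. FWHM 0 is the bit-exact identity.
Default FWHM 6 mm (a config input; the effective reconstructed resolution,
not the printed voxel size).

## PSD volumetrics

Volumes are voxel count × voxel volume in cm³. Subsegmentation cuts the PSD
mask with three planes in a right-handed x=LR / y=PA / z=IS voxel frame: an
oblique plane through the pituitary and the corpus-callosum rostrum whose
normal lies in the mid-sagittal plane (prefrontal ventral / frontal dorsal),
and coronal planes through the central-sulcus apex (frontal/parietal) and
the parieto-occipital fissure (parietal/occipital). Planar cuts approximate
the true curved sulcal surfaces, which cannot be recovered from landmark
points alone. Boundary voxels go to the more anterior/dorsal compartment
(deterministic tie-break). The partition is complete and disjoint by
construction. ICV adjustment is the plain volume/ICV fraction.

## Statistics

Anderson–Darling normality with estimated parameters: A*² =
A²·(1 + 0.75/n + 2.25/n²), p from the standard piecewise-exponential
approximation (the adjusted statistic is returned). Spearman correlation
uses mid-ranks with a two-sided t approximation at n−2 df, replaced by
exhaustive permutation enumeration for n ≤ 7. Partial Spearman
rank-transforms x, y and the covariates (binary covariates such as 0/1 sex
pass through — ranking a binary is affine and changes nothing),
residualises the ranked x and y on the ranked covariates by least squares,
and correlates the residuals with n−k−2 df. Benjamini–Hochberg adjustment
is the usual step-up with cumulative-minimum monotonicity. Missing values
are dropped pairwise per test, so each test reports its own n. These four
are implemented in-package because they *are* the reproduced battery;
statsmodels, scipy and pingouin serve as independent cross-checks in tests.

## Synthetic data: what it emulates, what it does not

* **Reference TAC**: bi-exponential A·(e^(−λ₁t) − e^(−λ₂t)) (A = 25,
  λ₁ = 0.03, λ₂ = 0.25 min⁻¹) — a plausible cerebellar shape; only the
  shape matters to reference-tissue fitting, so no arterial input function
  is modelled.
* **PET noise**: additive Gaussian with SD = scale·√(activity/frame
  duration), the standard surrogate for reconstructed-PET noise; scanner
  resolution is emulated by an optional Gaussian blur of each frame before
  noise. No sinogram/reconstruction modelling.
* **ASL**: the per-label difference signal is the closed-form inversion of
  the CBF equation at each slice's effective PLD; Gaussian noise per
  volume. No MR physics (k-space, coils, suppression pulses).
* **Phase contrast**: plug or blunted-parabolic pulsatile flow in a tube
  ROI, phase wrapping into (−π, π], optional phase noise. No eddy-current
  background phase, no through-plane angulation.
* **Cohorts**: (BP_ND, PSD volume) from a Gaussian copula with latent
  Pearson ρ = 2·sin(π·ρ_S/6) — exact for bivariate normal — so the
  population Spearman equals the target (default 0.529). Marginals follow
  the study cohort (BP_ND 0.553±0.349, PSD 11.85±2.16 cm³, perfusion
  27.72±2.16 ml/100 g/min, net flow 0.686±1.254 ml/min, ages 56–78, 10/23
  male); physically non-negative quantities use truncated-normal quantile
  transforms (strictly monotone, Spearman-preserving); net flow is left
  untruncated because retrograde flow occurs. Perfusion and flow are
  independent of BP_ND (the null the cohort analysis should not reject);
  SUVr is affine in BP_ND plus noise, mirroring the tight static/dynamic
  agreement. Subregion volumes are fixed fractions of the total implied by
  the cohort subregion means.
* **Head phantom** (end-to-end runs): schematic nested ellipsoids and boxes
  on a 32×64×32 grid of 2-mm voxels — not anatomical. The PSD strip is
  carved voxel-exactly to each subject's target volume with subregion zones
  laid out along y so the landmark planes separate them. Tissue and
  intracranial volumes scale monotonically with the cohort targets;
  absolute phantom volumes are far smaller than human ones, which is
  irrelevant to rank statistics but means absolute volume comparisons with
  human cohorts are meaningless. A single integer atlas cannot hold
  overlapping masks, so ICV is measured as total non-background head volume
  and GM+WM as the sum of the tissue labels. All regions share one true
  k2′ (the regime SRTM2 assumes), and white matter carries BP_ND = 0.3
  (non-specific tracer retention) so the k2′ median is defined even for
  low-binding subjects. The reference TAC for fitting is the GTM-corrected
  cerebellar regional TAC: the cerebellar phantom region is small, and a
  raw spilled reference would inflate every downstream binding estimate.

Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions plus well-behaved noise — not robustness to
motion, registration error, segmentation error or physiological confounds,
all of which are out of scope (masks and landmarks are inputs).

## Problem sizes and determinism

Default end-to-end runs use 24 subjects; phantom validations use small
two/three-region grids; copula calibration uses n = 5000 and the Spearman
null calibration 5000 replicates at n = 23. All randomness flows from
per-operation `numpy` Generators seeded from one configured seed
(per-subject seeds are spawned from it), so every table is bit-reproducible
under a fixed config. Parametric SRTM2 maps in the pipeline use the basis
grid without scalar polish (`srtm_refine: false` by default) — standard for
parametric imaging and ~10× faster; region-level fits and the recovery
validations keep the polish.

## Known limitations

* The unaliasing median reference fails if more than half the ROI wraps at
  some cardiac phase (it raises rather than guessing); multi-wrap
  velocities (> 2·VENC) are out of the modelled regime.
* GTM exactness holds for the matched PSF; PSF mismatch between data and
  correction biases means (exercised deliberately in the phantom, not
  corrected).
* The t approximation for Spearman p is mildly conservative at n ≈ 23 with
  heavy ties; the exact enumeration only engages for n ≤ 7.
* Landmark planes are planes: strongly curved central sulci are
  approximated, and the prefrontal/frontal split direction follows the
  declared mid-sagittal-normal convention.
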