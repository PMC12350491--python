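# Methods

## Scope

`lungdce` analyzes 4-D DCE-MRI series of lung tumors acquired with fast
view-sharing protocols whose frame spacing is deliberately non-uniform
(~1.3 s through the bolus, ~10 s afterwards). Inputs are a signal series, a
tumor mask, acquisition metadata, and per-patient labels; motion correction
and segmentation are assumed done upstream. The package also generates
synthetic cohorts with known ground truth, which back all quantitative
claims made by its test suite.

## Signal model

The spoiled gradient-echo steady-state equation links signal to the
longitudinal relaxation rate,

    S = M0 sin(a) (1 - E) / (1 - cos(a) E),   E = exp(-TR * R1),

with R1(t) = 1/T10 + r1 * C(t). The full nonlinear inversion is used rather
than the linear low-concentration approximation: at TR ≈ 2.25 ms and
a = 25°, the linear form misestimates peak tumor concentrations
appreciably. M0 sin(a) is fixed from the pre-bolus baseline frames (the
frames preceding the estimated bolus arrival, minimum one), so only the
signal ratio to baseline enters. Negative concentrations produced by noise
are retained so residual statistics stay unbiased; only samples outside the
SPGR-attainable range are clamped (to R1 in [1e-6, 1e3] s⁻¹) and flagged
per-frame. Defaults T10 = 1.4 s and r1 = 3.6 L·mmol⁻¹·s⁻¹ are literature
values for lung tissue and gadoterate at 1.5 T; both are configurable
because site calibrations differ. No B1 or multi-flip T1 mapping is
attempted.

## Arterial input functions

Three population AIF forms are shipped (constants in
`lungdce/aif_constants.json`, all overridable):

- **weinmann** — bi-exponential plasma decay `D(a1 e^{-m1 t} + a2 e^{-m2 t})`
  with the classic constants (a1 = 3.99, a2 = 4.78 kg/L; m1 = 0.144,
  m2 = 0.0111 min⁻¹), scaled by the injected dose (default 0.1 mmol/kg,
  i.e. 0.2 mL/kg of a 0.5 M agent). Published as plasma concentration.
- **parker** — two Gaussian bolus passes plus a sigmoid-gated exponential
  washout with the published population constants; whole blood.
- **georgiou** — a gamma-variate bolus-pass sum plus a sigmoid-gated
  exponential approach to equilibrium; whole blood. The shipped constants
  are *representative*, chosen for physiological morphology (first-pass peak
  ≈ 6 mM blood ~0.25 min after arrival, 10–90% rise ≈ 7 s matching a
  3–4 mL/s injection, recirculation shoulder, slow tail) rather than
  transcribed from a specific calibration, and should be overridden where a
  site calibration exists.

Whole-blood forms are divided by (1 − Hct), default Hct = 0.42, to yield the
plasma concentration the Tofts models require; the Weinmann form is already
plasma and is not corrected. All forms are causal in the bolus delay: the
curve is exactly zero before t0. Subject-specific AIF extraction is out of
scope — tumor-focalized acquisitions rarely contain a usable artery.

## Bolus arrival time

Three estimators operate on the mean-tumor signal curve (never voxel-wise),
using divided differences with the actual frame spacing since the grid is
anisotropic:

- **LL** fits a flat-baseline + linear-upslope model over [first frame,
  signal peak] by exhaustive breakpoint search (ties toward the earliest
  breakpoint).
- **LQ** replaces the upslope by a quadratic joining the baseline with value
  and slope continuity; its window ends where the curve reaches 20% of its
  total rise (configurable) because a quadratic describes only the initial
  enhancement — extended to the peak it drags the breakpoint several seconds
  early.
- **PG** smooths with a 3-point moving average, finds the maximum forward
  gradient before the peak, walks back to where the gradient first drops
  below 10% of that maximum, and refines the onset sub-frame by linear
  interpolation of the threshold crossing. Smoothing and interpolation are
  switchable; on ideal step inputs the raw un-interpolated variant localizes
  the jump exactly.

Monte-Carlo on rendered cohorts (SNR 20, 200 replicates) shows LQ and PG
recover a known delay within one fast frame in ≥ 99% of cases. LL does
not: on tissue curves the onset is convex (the vascular term plus the
convolution tail rise like a power of t), and the best piecewise-linear
breakpoint carries a systematic lag of one to two fast frames whatever the
window. This is an intrinsic limitation of the LL formulation, documented
rather than patched; the delay is in any case refined as a free fit
parameter afterwards, which absorbs most of the initialization error.

A curve whose total rise does not clear a robust noise floor (5× a
median-absolute-difference estimate) raises a no-bolus error.

## Pharmacokinetic fitting

The convolution is evaluated on a uniform internal grid (default 0.5 s)
anchored at the bolus delay, so the AIF onset — a jump for the
bi-exponential form — sits exactly on a node. On that grid the exponential
kernel integral is computed by the exact piecewise-linear recursion,
implemented as a first-order IIR filter; halving the step changes fitted
Ktrans by < 0.5%, and against the closed-form convolution available for
bi-exponential AIFs the maximum error is below 1e-4 mM over 10 min. The
ETM vascular term is evaluated analytically at the sample times.

Fitting uses `scipy.optimize.least_squares` (trust-region-reflective) over
(Ktrans, Kep, [Vp,] t0), with Ve = Ktrans/Kep derived — this avoids the
Ve → 0 singularity of the (Ktrans, Ve) parameterization. Bounds:
Ktrans ∈ [0, 5] min⁻¹, Kep ∈ [1e-3, 20] min⁻¹, Vp ∈ [0, 0.5], and t0 within
±10 s of the BAT initialization; starting point (0.2, 1.0, 0.02, t0_init).
The ranges bracket reported lung-tumor values with wide margins. Degenerate
inputs (non-finite or constant curves) return an unconverged result whose
undefined R² is treated as ≤ 0 downstream. For model comparison on
mean-tumor curves the ETM fit adds a second start at the TM solution with
Vp ≈ 0, which enforces the nested-model property (ETM R² ≥ TM R²) even when
the default start lands in a local minimum; voxel-wise fits use the fast
single start.

Fit quality is the coefficient of determination computed on the
concentration curve (the fitted quantity). The configuration grid fits the
mean-tumor curve of every patient under all 18 model × AIF × BAT cells and
ranks configurations by median R² across patients; ties prefer the
simpler model, then lexicographic order.

## Features and statistics

Voxels with R² ≤ 0 are excluded — this is the operational definition of
necrotic/outlier tissue — as are voxels with a non-physical derived Ve > 1.
Remaining voxels yield median, 90th percentile (linear interpolation
between order statistics), and population SD (ddof 0) per parameter map:
12 features per patient. Both conventions are fixed for bit-reproducibility
and switchable.

The statistical layer mirrors a conventional exploratory biomarker
analysis. Mann–Whitney U uses the exact permutation null for tie-free
samples with total n ≤ 16 and the tie-corrected normal approximation
otherwise; Kruskal–Wallis applies the tie-corrected H with a chi-square
reference. ROC analysis orients the positive class toward the group with
the higher feature median, reports the trapezoid AUC (identical to
U/(n₁n₂) on tie-free data), a seeded stratified bootstrap percentile 95% CI
(default 2000 resamples), and an operating point maximizing Youden's J with
ties resolved toward higher specificity (a max-accuracy rule is available).
Lin's CCC uses population moments with the > 0.85 high-reproducibility
flag. Bivariable logistic regression fits label ~ feature + covariate one
covariate at a time (histology dummy-coded), flags complete separation
explicitly, and reports whether the feature's Wald p stays below 0.05.
**No multiple-testing correction is applied** (12 features per threshold);
every report marks significance as uncorrected and exploratory.

## Synthetic cohorts

The generator emulates the acquisition geometry (30 frames: 25 at 1.34 s
then 10 s spacing; TR 2.25 ms; flip 25°) and a two-group cohort structure:
38 patients with 13 PD-L1 hyperexpressors (TPS ≥ 50%) by default, TPS drawn
as a mixture so the 1% threshold also partitions the cohort (13 : 12 : 13
across < 1%, 1–50%, ≥ 50%), histology 14/12/12 across
adeno/squamous/poorly-differentiated, and 34/38 node-positive.

Tumors are ellipsoids with log-normal voxel kinetics around log-normal
patient-level medians. Group medians mirror the contrast reported between
PD-L1 hypo- and hyper-expressing lung tumors: Ktrans 0.25 vs 0.12 min⁻¹,
Ve 0.23 vs 0.20 (hence Kep ≈ 1.09 vs 0.59 min⁻¹, derived as Ktrans/Ve so
the voxel maps stay mutually consistent), Vp ≈ 0.008 in both. Spreads
(voxel-level log-SD 0.8/0.3/0.8 for Ktrans/Ve/Vp; patient-level 0.4/0.15/
0.3) were chosen once so that the simulated SD and 90th-percentile features
land in the reported range; with them the patient-level Ktrans separation
corresponds to a true AUC near 0.9. A default 5% of tumor voxels are
necrotic: rendered as baseline plus noise only, they carry no kinetic
signal. Noise is additive Gaussian on the magnitude signal at 5% of
baseline (SNR 20) — tumor SNR is high post-contrast, so a Rician model
would differ negligibly. Bolus delays are drawn uniformly from 4–12 s.

Everything is a pure function of (config, seed); identical seeds give
bitwise-identical cohorts.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: respiratory/cardiac motion and
registration residue, k-space view-sharing temporal blur, coil and
bias-field inhomogeneity, B1/flip-angle error, partial-volume mixing at the
tumor rim, AIF miscalibration (the truth AIF is one of the fitted forms),
and segmentation ambiguity beyond simple mask dilation.

On the R² ≤ 0 exclusion: for necrotic (noise-only) voxels a bounded
4-parameter fit beats the mean predictor on roughly half of noise draws, so
the filter removes necrosis *preferentially* (their R² clusters near zero,
enhancing voxels near one) but not exhaustively; surviving necrotic voxels
contribute near-zero rate constants to the features. This behavior is
asserted as measured, not idealized.

## Problem sizes

Simulation sizes used by the validation suite and summary script are
desk-scale choices: rendered volumes of 6–12 voxels per axis (lesions of
~40–100 voxels), 6-patient noiseless cohorts for the configuration grid,
500 voxels for parameter recovery, 200 replicates for BAT recovery, 1000
null replicates for test calibration, and 20 replicate 38-patient cohorts
for the stratification rehearsal. Effect sizes, noise, and acquisition
timing are never reduced — only the number of voxels and replicates.

## Known limitations

- The Georgiou-form AIF ships representative constants, not a transcribed
  calibration; absolute Ktrans values depend on the AIF choice and scale.
- LL bolus-arrival estimation is systematically late by one to two fast
  frames on smooth tissue onsets (see above).
- The R² ≤ 0 necrosis filter is preferential, not exhaustive.
- Mean-tumor fits of heterogeneous lesions estimate a curve-level average
  that is not exactly the mean of voxel parameters (the model is nonlinear
  in its parameters).
- No spatial regularization, no 2CXM/Patlak alternatives, no DICOM
  ingestion (NIfTI only), no motion simulation or correction.
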