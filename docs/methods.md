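# Methods

This note documents the models implemented in `cvrquant`, the assumptions
behind the synthetic-data generator, the defaults that matter, and the
numerical choices made where the design was open.

## Study design emulated

The package targets a two-group, pre/post crossover design: caffeine-naive
and caffeine-habituated participants (8 per group; 3M/5F and 5M/3F), each
measured once before and once ~30 min after a 200 mg caffeine dose. Each
session yields (1) a block-design hypercapnia BOLD scan with simultaneous
capnography, (2) a three-scan phase-contrast (PC) flow session, and (3) a
TRUST venous-oximetry scan. The gas challenge is 5% CO2 inhalation.

Protocol defaults (`cvrquant.protocol`):

- **BOLD**: TR 1.5 s, 200 dynamics (300 s); blocks 15 s room air, 55 s
  hypercapnia, 75 s room air, 55 s hypercapnia, then room air. The block
  literature values sum to 275 s; the final room-air phase is extended to
  100 s so the schedule covers the full scan — the trailing frames are
  recovery baseline either way.
- **PC**: three back-to-back 60 s scans; room air during the first, the gas
  switched at 60 s. The first and third scans quantify CVR; the second
  falls in the physiological transient and is parsed but excluded.
  venc 40 cm/s (room air) and 60 cm/s (hypercapnia).
- **TRUST**: effective echo times 0/40/80/160 ms, 3 label/control pairs.
- **Capnograph**: 20 Hz sampling.

## End-tidal CO2 extraction (`capno`)

Breaths are local maxima of the trace separated by ≥ 2 s (assuming ≥ 15
breaths/min) with prominence ≥ max(1 mmHg, 25% of the trace range);
detection uses `scipy.signal.find_peaks`. The end-tidal value is the
maximum sample of the breath; the breath *time* is refined to sub-sample
precision by a least-squares parabola over ±0.5 s around the discrete
maximum, because the waveform is nearly flat at the plateau and the
discrete argmax jitters by a sample or two under instrument noise. The
envelope is linearly interpolated between breaths and constant-extrapolated
at the edges.

Scalar summaries: `mean_etco2` is the arithmetic mean of the resampled
(duration-weighted) envelope; `baseline_etco2` is the mean of its lowest
25% of samples — computed after time-shift alignment, on the
scan-overlapping segment; `delta_etco2` is mean − baseline, or the
hypercapnic-block mean minus baseline when a protocol is supplied. Per-scan
EtCO2 values for the flow CVR are breath-wise means over each scan's
acquisition window.

## Flow-based CVR (`pcflow`)

Flux is the ROI sum of through-plane velocity times voxel area
(`Σv · area · 0.01 · 60`, ml/min), positive along the ROI-median flow
direction. Unit-mass CBF divides by the SSS share of whole-brain drainage
(0.46), brain volume from structural imaging (a metadata input), and tissue
density (1.06 g/ml). CVR is the percent CBF change per mmHg EtCO2 rise;
brain volume cancels, so flux and CBF give identical CVR.

Venc aliasing is corrected inside the ROI with a near-limit heuristic:
voxels opposing the ROI-median direction whose value lies within 0.5·venc
of the opposite encoding limit are shifted by 2·venc toward the dominant
direction. This recovers single wraps up to 1.5·venc true velocity and is
idempotent; the threshold is configurable. ROI masks are supplied files (in
the emulated study they are drawn manually on the complex-difference
image); a top-percentile magnitude-threshold helper exists for synthetic
tests but is not used for quantification, since it misses dim edge voxels
and would bias flux low.

## BOLD-CVR mapping (`boldcvr`)

Preprocessing is deliberately light: motion correction is an identity hook
(synthetic data are motion-free), the brain mask keeps voxels whose
temporal-mean intensity exceeds 20% of the robust (98th-percentile)
maximum, and optional Gaussian smoothing is mask-normalized
(`G(data·mask)/G(mask)`) so a uniform brain is invariant.

Alignment estimates one global shift per scan: Pearson correlation between
the mask-mean BOLD time course and the envelope resampled at `t − s`, on a
grid (default ±30 s, 0.1 s steps), after projecting the constant and linear
drift out of *both* signals — a one-sided detrend leaves the envelope's own
trend in the correlation denominator and measurably biases the argmax. The
discrete maximum (ties toward the smallest |s|) is refined by a parabola
through the peak and its neighbors, giving sub-step precision. If the best
correlation is below 0.2 the shift is considered unreliable; the default
policy warns and falls back to s = 0 (configurable to raise).

The per-voxel GLM regresses the signal on `[1, centered EtCO2, ℓ]`, with
`ℓ = −(N−1)/2, …, (N−1)/2` in unit steps (the drift term is a zero-centered
ascending sequence). The map

    CVR = β1 / (β0 − β1·(mean − baseline)) · 100    [%/mmHg]

references the index to the room-air state rather than a virtual zero-CO2
state: subtracting `β1·(mean − baseline)` converts the intercept (the
signal at the *mean* regressor value) to the baseline-state signal. With
the generator's forward model this referencing makes noiseless recovery of
the configured CVR exact. Voxels with a non-positive denominator are
flagged invalid and excluded from ROI means (not clipped). ROI summaries
are means over valid voxels of user-supplied native-space masks; no
template normalization or atlas parcellation is performed.

CVR values can be normalized for basal EtCO2 and EtCO2 rise with a
multiplicative linear correction, defaults +2%/mmHg around a 38.1 mmHg
reference baseline and +4%/mmHg around an 8 mmHg reference rise; the
functional form of this adjustment is a package choice (the coefficients
and references are config-exposed) since only the sensitivities, not the
formula, are established.

## TRUST oximetry (`trustox`)

Control − label differences are averaged over pairs per eTE; static tissue
cancels. The 4 brightest ROI voxels on the shortest-eTE difference image
(deterministic index-order tie-break) are spatially averaged, and
`S0·exp(−eTE/T2)` is fitted by nonlinear least squares
(`scipy.optimize.curve_fit`) initialized from the log-linear regression (or
a configurable T2 start when signals are non-positive). No T1 correction
across eTEs is applied.

T2 converts to venous oxygenation through a strictly monotone quadratic
rate model `R2(1/s) = A(Hct) + B(Hct)(1−Yv) + C(Hct)(1−Yv)²` with
Hct-linear coefficients, inverted analytically on its monotone branch over
Yv ∈ [0.2, 0.98]. The shipped default coefficients are **synthetic
placeholders** with plausible output (T2 ≈ 57 ms at Yv = 0.608,
Hct = 0.40); real analyses should load an empirically calibrated model from
YAML. All correctness tests are round-trip based, so the processing chain
is independent of the particular coefficients. Hematocrit defaults to 0.40
(female) / 0.42 (male).

## Davis-type forward model (`hemodyn`)

`ΔBOLD/BOLD0 = k·CBV0·[dHb]0^β·(1 − (CBF_HC/CBF_0)^(α−β))`, with
`[dHb]0 ∝ 1 − Yv0` unless supplied directly. Defaults α = 0.38, β = 1.5 are
conventional 3 T values, not fitted quantities; k is unidentifiable and
fixed at 1. The model reproduces the attenuation asymmetry: when an
intervention both weakens the fractional CBF response and lowers baseline
venous oxygenation, the raised `[dHb]0` partly offsets the flow deficit, so
the predicted BOLD-CVR reduction is strictly smaller (signed) than the
flow-CVR reduction across α ∈ [0.2, 0.5], β ∈ [1, 2]. With the full
observed oxygenation drop (0.608 → 0.469) the offset actually
overcompensates at large β — the model then predicts a BOLD-CVR *increase*
— so the magnitude comparison |ΔBOLD%| < |ΔCBF%| is guaranteed only near
the conventional exponents; the directionality statement is what the model
supports in general. The first-order expansion
`response ≈ k·CBV0·[dHb]0^β·(β−α)·(r−1)` is accurate to 1% only for flow
ratios r ≲ 1.005 at β−α ≈ 1.1 (the Taylor remainder is ~1% at r = 1.01,
~2% at r = 1.02).

## Cohort statistics (`cohortstats`)

Percent change uses the reduction-positive convention
`(pre − post)/pre · 100`. Paired and independent t-tests are two-sided;
the independent test defaults to Welch (pooled on request). Identical
paired vectors return t = 0 with p = 1 by convention. The mixed model
`outcome ~ caffeine * group + sex + age + (1 | subject)` (caffeine pre=0 /
post=1, group naive=0 / habituated=1, sex F=0 / M=1) is fitted by REML via
statsmodels MixedLM. Fixed-effect inference uses Wald-z intervals by
default, with a residual-df t option; in balanced designs the coefficient
estimates coincide with OLS regardless of the variance components, and the
coefficients — not the p-values — are the quantities the recovery tests
check. Near-singular fits (vanishing random-intercept variance) are
flagged, not hidden.

## Synthetic-data generator (`synthgen`)

What it emulates, and the defaults:

- **Capnograph**: raised-cosine breaths (period 4 s, trough 2 mmHg) whose
  per-breath end-tidal level is the gas-block level at the moment of the
  breath peak — so the envelope ramps to the hypercapnic level within one
  breath of block onset — plus breath-to-breath physiological jitter
  (SD 0.5 mmHg) and small instrument noise (SD 0.1 mmHg). The jittered
  envelope is the *true arterial drive*: the BOLD forward model consumes
  it, and only the instrument noise separates the capnograph measurement
  from it. Treating measurement noise as physiological drive would build
  regression dilution into the ground truth itself.
- **BOLD**: the forward model is the regression model — voxel signal
  `β0·(1 + CVR/100·(EtCO2(t − delay) − EtCO2_RA))` plus linear drift and
  white Gaussian noise; no hemodynamic convolution (the analysis model
  assumes a shifted, not convolved, regressor). Defaults: 16×16×8 grid
  with an ellipsoidal brain, β0 = 1000, noise SD 10 (1% of baseline),
  drift slope ~ N(0, 0.05)/dynamic, delay uniform in 4–8 s. The grid is
  configurable; the default keeps a full cohort replicate in tens of
  milliseconds per subject.
- **PC**: an elliptical sinus (semi-axes 11×9 voxels of 0.4 mm, ≈50 mm²)
  with a parabolic velocity profile scaled so the discrete ROI integral
  equals the configured flux exactly before noise (velocity noise
  SD 0.3 cm/s); velocities beyond venc are stored wrapped by 2·venc. The
  generator refuses configurations whose ROI-mean velocity exceeds 2·venc
  or whose peak reaches 3·venc (unrecoverable by a single unwrap).
- **TRUST**: static tissue identical in label and control; sinus blood
  `S0·w·exp(−eTE/T2)` with a 2×2 full-signal core (w = 1) and a
  partial-volume ring (w = 0.6), S0 = 1000, noise SD 15. T2 comes from the
  calibration at the configured Yv and Hct, so generator and estimator
  share no code path beyond the calibration itself (estimation is tested
  against brute-force oracles).
- **Cohorts**: per subject and measure, (pre, post) values are drawn from
  bivariate normals with the configured group means/SDs and a
  within-subject correlation of 0.7 (chosen so simulated paired tests have
  power comparable to the reported findings; per-state SDs alone do not
  pin it down). Group configurations: CBF-CVR naive 4.5±0.9 → 3.0±0.9,
  habituated 5.1±1.5 → 3.7±1.3 %/mmHg; Yv naive 60.8±9.2 → 46.9±3.7%,
  habituated 53.6±3.9 → 49.6±6.6%; whole-brain BOLD-CVR (reported pooled
  only, applied to both groups) 0.17±0.04 → 0.15±0.05 %/mmHg. Basal-CBF
  *means* are not reported anywhere; the defaults (naive 62.0±15.4 →
  42.7±10.6, habituated 55.0±5.9 → 45.8±4.9 ml/100 g/min) are realistic
  young-adult values consistent with the reported percent reductions
  (31.2% / 16.7%) and pre-state SDs. Subject-level EtCO2: baseline
  N(38.1, 3.0) mmHg, hypercapnic rise N(8, 1) mmHg; brain volume
  N(1250, 100) ml. Redraw bounds exist only to keep rendering valid
  (positive fluxes, calibration domain) and are wide enough that
  truncation of the configured normals is negligible — tight bounds would
  bias the realized group means.

What the generator does **not** emulate: subject motion, cardiac and
respiratory nuisance cycles, partial-volume and draining-vein effects in
BOLD, background phase offsets and multi-vessel anatomy in PC, B0/B1
inhomogeneity, and any nonlinearity between EtCO2 and the hemodynamic
response. Passing recovery tests therefore demonstrate that the estimators
are unbiased and correctly implemented *under the stated forward models* —
not that the pipeline is robust to everything real acquisitions contain.

## Numerical choices

- GLM: `numpy.linalg.lstsq` per voxel (vectorized over voxels), verified
  against an explicit normal-equations oracle to 1e-8.
- Alignment: both-sides constant+linear projection before correlation;
  sub-step parabolic peak refinement; correlation floor 0.2 with
  warn-and-zero fallback.
- T2 fit: log-linear initialization, Levenberg–Marquardt refinement,
  verified against a T2×S0 grid-search oracle to 0.5%.
- Bottom-quartile baseline: `ceil(0.25·n)` lowest samples, at least one.
- Tie-breaks: voxel selection by ascending flat index; shift ties toward
  the smallest |s|.
- Degenerate inputs raise typed errors (`ParameterError`, `ShapeError`,
  `SignalQualityError`, `DomainError`, `AlignmentError`) rather than
  propagating NaNs; zero-variance paired tests return the documented
  t = 0 / p = 1 convention.

## Replicate sizes

The recovery checks (tests and `scripts/acceptance.py`) use 200 seeded
replicate cohorts per target — 1600 subject-sessions per flow/oximetry
target and 3200 rendered BOLD scans for the pooled BOLD-CVR targets — at
the default 16×16×8 BOLD grid and 64×64 PC grid. Grand means are compared
to the configured group means within three Monte-Carlo standard errors of
the replicate means. These sizes keep the full recovery surface a
few-minute computation while leaving Monte-Carlo error well below the
effect sizes of interest.
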