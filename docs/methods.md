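# Methods

## The calibration problem

Given absorbance spectra A(ν) in log(1/R) over an instrument grid and a
reference component value y (%, dry basis) per sample, a calibration
model maps spectra to composition.  The limiting resource is reference
chemistry: Kjeldahl protein, HPLC sugars and similar assays cost hours
per sample, so a method that reaches quantitative accuracy (RPD > 3)
with ~30 analysed samples instead of hundreds changes what is feasible
in a breeding programme.

## The prediction–correction network

All models here operate on the first k principal-component scores of the
(optionally wavelength-masked) spectra.  The PCNN is two single-hidden-
layer perceptrons sharing that score space:

1. **Prediction network (PNN).**  Trained on s synthetic standard
   mixtures — blends of purified amylopectin, protein, crude fiber,
   fructose, glucose and sucrose whose compositions are known exactly
   from weighing and span a wider range than real kernels.  Loss₁ is the
   mean squared error of the min–max-scaled targets over the s
   standards.
2. **Correction network (CNN).**  Real samples deviate from the
   standards world: kernel-matrix absorption, instrument presentation,
   and a systematic offset plus random error in the wet-chemistry
   reference scale.  The CNN is trained on the calibration residuals
   y − PNN(z), computed in original units and re-scaled with their own
   min–max statistics; Loss₂ is their mean squared error over the p
   calibration samples.

The estimate for any sample is ŷ = y⁰ + yᵉ with both parts
inverse-scaled to original units before the addition; the additivity is
exact by construction.  The division of labour is the point: the PNN
learns the (possibly nonlinear) spectra→composition map where reference
values are free and exact, and the CNN only has to absorb the
*systematic* standards-vs-kernels discrepancy, which is a far smaller
function to estimate from ~30 noisy points than the full map.

### Assumptions

- The standards span the spectral variation of real samples: every
  direction along which kernels vary must also vary in the standards
  (composition) or be shared instrument behaviour seen by both.  During
  development we verified the converse experimentally: adding
  kernel-only variation directions (minor constituents absent from the
  standards) collapses the PNN's transfer completely.  This is the
  method's hard precondition, not a tunable.
- The discrepancy between domains is smooth in score space and mostly
  systematic; per-sample random reference error cannot be corrected and
  sets the accuracy floor.

## Preprocessing

- **Wavelength selection**: keep grid points with |Pearson r| >
  threshold between absorbance and the component over the calibration
  set only (never validation — no leakage).  Threshold 0 keeps the full
  spectrum; default 0.3.  Zero-variance columns get r = 0 so the mask is
  total.
- **PCA**: one mean-centred SVD basis fitted on the union of standard
  and calibration spectra, so standards, calibration and validation
  samples live in one coordinate system; k defaults to 26, capped at the
  attainable rank.  Validation spectra are only projected.
- **Scaling**: component targets are min–max scaled to [0, 1] — PNN
  targets with the standards' statistics, CNN residual targets with
  their own — and never clipped; predictions are reported in original
  units.

## Networks and training

y = W²σ(W¹z + b¹) + b², with σ ∈ {tanh, swish, ReLU, leaky-ReLU
(slope 0.01)}.  Weights are initialised from a seeded symmetric uniform
distribution with Glorot fan scaling; biases start at zero.  Training is
full-batch Adam (lr 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) — calibration
sets are tens of samples, so batching would only add noise.  Training is
bit-reproducible for a fixed seed.  Network inputs are the raw PC
scores: an experiment with per-PC standardisation degraded
generalisation badly, because it inflates low-variance noise directions
relative to the natural PCA variance weighting.

Benchmark defaults (protein): PNN 20 neurons / tanh / 10 000 epochs —
chosen by training until the held-out standards error plateaus; CNN 2
neurons / tanh / 1 000 epochs — narrow and briefly trained on purpose,
so it captures the smooth residual structure without interpolating
reference noise; ANN baseline 9 neurons / tanh / 4 000 epochs.  The
shipped per-component configuration tables for real fresh-maize traits
(e.g. protein ANN 9/ReLU/4000; protein PCNN 10/tanh/300 + 2/tanh/3000)
are documented defaults for that instrument/regime and are exercised in
the tests.

## SELECT sampling

Pairwise Mahalanobis distances between PC scores,
D(i,j) = sqrt((zᵢ−zⱼ)ᵀΣ⁻¹(zᵢ−zⱼ))/sqrt(k) with Σ the score covariance
ridge-regularised by 1e-8·trace/k.  The sqrt(k) normalisation keeps
typical distances O(1) regardless of k; the exact standardisation used
by commercial SELECT implementations is unpublished, so absolute NH
values are not transferable between data sets — use
`nh_for_target_count` to pick NH by the calibration size you want
(the benchmark bisects to ~32).  A single greedy pass in dataset order
retains a sample unless it lies within NH of an already-retained one
(≤ rule: NH = 0 removes exact duplicates only; first seen wins ties).
Invariants: retained pairs are > NH apart, every discarded sample is
within NH of its recorded absorber, and the retained count is
non-increasing in NH.

In the benchmark, SELECT distances use the leading 10 PCs: whitening all
26 gives low-variance noise/baseline-artifact directions equal weight,
and "diversity" degenerates into picking artifact outliers.

## Nonlinearity diagnostics

Residuals of an OLS fit of the component on the first k PC scores,
ordered by ascending reference value, feed two tests:

- **Runs test**: z = (r − μ + 0.5)/σ with μ = 2n₁n₂/(n₁+n₂) + 1 and
  σ² = 2n₁n₂(2n₁n₂−n₁−n₂)/((n₁+n₂)²(n₁+n₂−1)).  The continuity
  correction is applied with a fixed +0.5 (the convention this
  implementation follows throughout), not the sign-adaptive textbook
  variant; the difference is a one-half-count shift in the rejection
  boundary.  Zero residuals are dropped before taking signs.  The
  normal approximation is only trusted for n₁ > 10 and n₂ > 10;
  otherwise the verdict is "underpowered".  μ and σ² are the exact
  moments of the run-count distribution — the test suite verifies them
  against complete enumeration for all n₁+n₂ ≤ 10.
- **Durbin–Watson**: d = Σ(eᵢ−eᵢ₋₁)²/Σeᵢ², d ∈ [0, 4], scale-free.
  Critical bounds (d_L, d_U) depend on n, the regressor count and α and
  are supplied by the caller; 1.738/1.799 ship as documented defaults
  for the large-n regime this package targets.  The acceptance suite
  instead derives an exact-size critical value by Monte-Carlo
  simulation of the null on the same design.

A component is flagged nonlinear if either test rejects, linear if both
accept, else inconclusive.

## Evaluation metrics

R² = 1 − SSE/SST; RMSE = sqrt(SSE/n) (1/n, including for validation);
S = sqrt(SST/(q−1)); RPD = S/RMSEV.  The denominators differ on
purpose — they follow the conventions of the field — which yields the
exact identity RPD = sqrt(q/((q−1)(1−R²_V))), used as a cross-check.
Percent improvements are reported as 100·Δ/baseline rounded half-up to
two decimals.  A perfect fit reports RPD as an infinity flag, not a
number.

## The synthetic benchmark

`simulate.benchmark_suite(seed)` reproduces the experimental shape of a
small-sample study from one seed; everything below is a fixed study
condition, not a tunable:

- **Pure spectra**: six absorptivity curves, each a sum of 8–15 Gaussian
  bands (widths 30–200 cm⁻¹, the width range of NIR overtone bands) on
  the 1557-point 3999.64–10001.03 cm⁻¹ grid, scaled so typical mixtures
  sit at O(1) absorbance.  Purity factors (e.g. 97.1 % amylopectin)
  multiply the nominal concentrations.
- **Standards (99)**: independent truncated-normal compositions with
  wide spreads (e.g. protein 12 ± 5.5 %), exact reference values.
- **Kernel samples (246)**: a three-type variety population
  (sweet / waxy / sweet-waxy at fractions 140/72/34) with
  starch/sugar mean shifts between types and narrower, correlated
  within-type spreads.  The multimodality is essential: it is what makes
  representative (SELECT) calibration sampling visibly better than
  random draws of the same size.
- **Shared instrument chain** (applied to standards *and* kernels —
  same spectrometer, same cups): multiplicative scatter (0.5 %),
  saturating detector response tanh(0.6·A)/0.6, a random cubic baseline
  (Legendre form, coefficient sd 0.02 AU) and heteroscedastic noise.
- **Kernel-only effects**: a broad matrix absorption band at 5150 cm⁻¹
  (mean 0.03 AU), a constant reference bias of −1.0 % protein (the
  offset between the gravimetric standards scale and the wet-chemistry
  scale), and wet-chemistry repeatability noise (sd 0.35 % protein).

The evaluation protocol shuffles the 246 kernels (10 seeded repeats),
holds out 51 validation samples, draws ~32 calibration samples by SELECT
(or size-matched random sampling) from the remaining 195, trains, and
averages RPD/R²_V/RMSEV.

### What the simulator does and does not show

Passing tests on this benchmark demonstrate the *mechanism*: with a
shared instrument chain and kernel-only systematic effects, the PCNN
recovers the injected reference bias to a few percent of its magnitude
and beats the small-sample ANN in most shuffles, and SELECT calibration
beats size-matched random sampling on average.  They do not certify
performance on real spectra: real NIR has richer nuisance structure
(moisture, particle size, temperature), true absorptivities are not random
Gaussian bands, and the margin between PCNN and a well-tuned small-
sample ANN varies with the random spectral library — some library seeds
make the target component cleanly separable, and then 30 real samples
are simply enough for a direct fit.  The canonical benchmark instance
(seed 1) is fixed and shipped; robustness across other seeds was
measured and is typical but not universal.

## Numerical choices and degenerate inputs

- PCA refuses k beyond the attainable rank and reports it; pipelines cap
  k at min(k, n−1, p, rank) automatically.
- Covariance for Mahalanobis distances is Cholesky-factorised after the
  ridge; singularity beyond that raises.
- Min–max scaling refuses constant vectors; RPD on a zero-RMSE fit is
  flagged infinite rather than returned as a number; percent changes
  refuse non-positive baselines.
- PLS latent count, when not given, is chosen by 10-fold CV RMSE on the
  calibration set, capped at 20 and at fold rank.
- Replicate spectra (repeated ids in a wide CSV) are averaged at read
  time; grids must be strictly monotone; resampling between instrument
  grids is linear interpolation and refuses extrapolation.  nm ↔ cm⁻¹
  conversion (10⁷/λ) is provided for cross-instrument harmonisation.

## Known limitations

- No scatter-correction preprocessing (SNV/MSC) or derivative filters;
  the method is evaluated on raw log(1/R) spectra.
- Durbin–Watson p-values (Pan's algorithm) and exact runs-test p-values
  for large n are out of scope; verdicts use bounds/critical values.
- The SELECT distance scale is an approximation of an unpublished
  standardisation; only the count-targeting helper is portable.
- Single-response models only (one component per fit); fit one model per
  trait.
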