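# Methods

This note documents the models, parameter choices and numerical decisions
behind `nirsicpp`, and what its synthetic-data experiments do and do not
demonstrate about real recordings.

## Study design being modeled

Dual-wavelength (775/855 nm) continuous-wave fNIRS over 10 prefrontal
channels at a 1 Hz acquisition rate, during a two-trial block paradigm:
2-s prompt, 30-s mental-arithmetic (MA) block, 2-s prompt, 30-s rest
block, twice — 128 s per subject. Subjects belong to a normal or an ICPP
group, each with female and male strata; clinical markers (LH, FSH,
estradiol for girls, testosterone for boys) are only archived for the
ICPP group. Trials for machine learning are the 60-s MA+rest
concatenation, prompts excluded.

## Synthetic cohort generator

The generator produces what the downstream analysis assumes, not a
biophysical head model.

Per channel, ΔHbO is the subject's true task amplitude β (μmol/l) times
the MA boxcar convolved with the canonical HRF, plus noise terms; ΔHbR is
the signal component scaled by −r (default r = 0.3), reproducing the
negative deoxy-hemoglobin response, plus its own r-scaled noise; ΔHbT is
their sum by definition. Noise comprises: a respiratory sinusoid
(0.25 Hz, 0.05 μmol/l), a Mayer-wave sinusoid (0.1 Hz, 0.08 μmol/l), a
random-slope linear drift (±0.002 μmol/l/s), white noise (SD 0.1 μmol/l),
and optional ~1-s motion spikes (Poisson-timed, ±2 μmol/l). Cardiac
pulsation (> 0.5 Hz) cannot exist at a 1 Hz sampling rate and is folded
into the white-noise term. All amplitudes are configurable
(`NoiseConfig`); the defaults are ordinary magnitudes for adult/pediatric
prefrontal recordings once scaled to μmol/l units.

Two group-level effects define the study conditions (`CohortEffect`):

1. **Task amplitudes.** Per-channel mean β by group × gender (normal
   groups higher and broader, female normal highest; two ICPP channels
   weakly recruited), between-subject SD 0.3 μmol/l.
2. **Negative network pair.** Channels 4 and 7 (1-based) share a slow
   0.05 Hz oscillation with opposite signs — the anticorrelated pair
   whose inverse synchrony the feature analysis keys on — with mean
   amplitude 0.35 μmol/l in the normal group and 0.15 μmol/l in ICPP
   (weakened inverse synchrony under the condition, consistent with the
   reduced-connectivity interpretation of the disorder). Without this
   structure a negative-correlation feature set has nothing systematic to
   measure in synthetic data.

Metadata are drawn from truncated Gaussians around the published cohort
summaries (age ≈ 10.7 ± 2.5 y, education ≈ 4.8 ± 2.4 y; LH 4.81 ± 3.47
IU/l, FSH 4.76 ± 2.30 IU/l, estradiol 118.6 ± 98.3 pmol/l, testosterone
12.75 ± 4.69 nmol/l for the ICPP group).

Raw intensities are generated by inverting the modified Beer–Lambert law:
`I(λ,t) = I₀·10^(−ΔA)` with
`ΔA = d·DPF(λ)·(ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR)`, d = 3 cm, DPF = 6.0 at
both wavelengths (configurable; the DPF value is a standard adult
default), and extinction coefficients interpolated from compiled
hemoglobin spectra (l·mmol⁻¹·cm⁻¹): ε(775) = {HbO 0.681, HbR 1.073},
ε(855) = {HbO 1.058, HbR 0.781}. Bad channels are emulated by a
multiplicative log-normal intensity wobble that pushes the channel CV
past the quality threshold.

**What the generator does not emulate:** superficial/systemic physiology
shared across channels, spatially correlated noise, cardiac pulsation,
subject-specific HRF variability, optode-coupling drift, or any real
anatomical channel layout. Passing tests on this generator demonstrate
that the pipeline's statistics behave as designed under its assumptions —
not that the classifier accuracies transfer to clinical recordings.

## Preprocessing

Order (as a pipeline default): quality screen → MBLL → detrend →
low-pass → TDDR.

- **Quality screen.** CV = σ(I)/μ(I)×100 per channel per wavelength
  (sample SD, ddof 1); a channel's CV is the maximum over the two
  wavelengths (the conservative choice; the per-wavelength vs combined
  convention is not standardized). A channel is bad when CV *strictly
  exceeds* 15%; any bad channel discards the subject.
- **MBLL.** The baseline I₀ is each channel's temporal mean intensity at
  each wavelength, so concentrations are mean-referenced: recovered ΔHb
  equals the true signal up to a per-channel constant. The 2×2
  extinction system is solved exactly; singular ε matrices are rejected.
- **Detrending.** Least-squares polynomial fit per channel (default
  order 1) on [−1, 1]-scaled time for conditioning; the residual has
  zero mean and is orthogonal to the basis.
- **Low-pass.** Third-order digital Butterworth at 0.1 Hz applied
  forward–backward (`sosfiltfilt`): zero phase, squared single-pass
  magnitude. Note that at fs = 1 Hz the bilinear-transform frequency
  warping matters: the two-pass gain at 0.2 Hz is
  1/(1+(tan 0.2π/tan 0.1π)⁶) ≈ 1/126, not the analog prototype's 1/65.
- **TDDR.** The published repair splits the signal at 0.5 Hz and
  robustly reweights the low-frequency temporal derivative. At a 1 Hz
  sampling rate 0.5 Hz *is* Nyquist, and applying the reweighting to the
  full fluctuation destroys the task response (block transitions are
  themselves derivative outliers). The implementation therefore holds
  out the hemodynamic component as a 5-s running-median baseline —
  robust to isolated spikes, transparent to smooth responses — and
  applies the iterative Tukey-biweight reweighting (tuning constant
  4.685 on deviations standardized by 1.4826·MAD; non-robust SD fallback
  when the MAD collapses to zero on sparse residuals) to the residual's
  derivative, reintegrates, and restores the baseline. Clean signals
  pass within ~0.3% RMS; 10× motion spikes are suppressed by ~99%.
  TDDR runs after filtering to mirror the documented processing order;
  the stage order is configurable.

## Activation analysis

The canonical HRF is the standard double-gamma kernel (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot ratio 1/6, 32-s
support), peak-normalized. The GLM design holds an intercept and the
HRF-convolved MA and rest boxcars (prompts unmodeled); n = 128 rows, p = 3
columns by default. Optional polynomial drift regressors can be added;
the pipeline matches their order to the detrending order, which makes the
task β invariant to the detrending stage (without this the detrend
projection biases β by ~13%; with it the full-chain noiseless recovery
bias is ≈ 2.5%, attributable to the low-pass acting on the data but not
the regressors).

Group inference uses paired t tests (β_MA vs β_rest per channel, per
group × gender) and two-sample t tests (pooled variance by default, Welch
optional) on β_MA between groups, with Benjamini–Hochberg step-up FDR
adjustment applied per test family and significance at adjusted p < 0.05.
Degenerate cases (zero-variance differences with a nonzero gap) raise
rather than returning NaN. Shapiro–Wilk and Levene checks are provided
for the β samples, and Pearson correlation links activation to clinical
markers. The power calculation exposes both the normal-approximation
formula (⌈2(z_{α/2}+z_β)²/d²⌉ = 63 at α = 0.05, power 0.80, d = 0.5) and
the exact noncentral-t solution (64); the one-participant discrepancy
between the two methods is inherent, not a bug, and both are reported.

## Feature extraction

Trials are the 60-sample MA+rest windows. All data-dependent transforms
are fitted on training trials only and frozen (`FeatureExtractor`);
transforming held-out data never refits, and tests assert this.

- **A** — per training trial, the most negative entry of the 10×10
  Pearson matrix votes for a channel pair; the modal pair wins (ties: more
  negative mean correlation, then lexicographic). Features are mean,
  sample variance (ddof 1), moment skewness g₁ and Fisher excess kurtosis
  g₂ of the two pair channels (conventions chosen as the field's defaults;
  constant signals report 0 with a degeneracy flag).
- **B** — per channel, PCA across trials (rows = trials, columns = time
  samples; mean-centered), first 3 component scores. Trials-as-rows is
  the interpretation that yields a fixed-length per-trial feature.
- **C** — A concatenated with the pair channels' 3 PCs (8 + 6 = 14).
- **D** — per channel and trial, EMD; IMFs aligned by index (first 3,
  zero-padded when fewer); per (channel, IMF index), PCA across trials
  keeps the PC1 score. IMF indices absent from all training trials score
  zero.
- **E** — per-trial GLM on the trial's own 60-s window (MA 0–30 s, rest
  30–60 s regressors); the 10 per-channel MA β values.

EMD is implemented as classical sifting: cubic-spline envelopes through
local extrema (plateau midpoints; end extrema mirrored), stop when the
normalized squared change between sifts falls below 0.2 (Cauchy-type
criterion), at most 50 sifts per IMF and 10 IMFs; decomposition stops when
the residue has fewer than two extrema. Completeness (ΣIMF + residue =
signal) holds by construction and is asserted to 1e−10.

## Classification

Splits are seeded shuffle-partitions at a 0.8 train fraction, by subject
(default; both trials of a subject stay together, preventing
within-subject leakage) or by trial; a stratified redraw guards against a
class stranded in one partition. Grid search is exhaustive over
documented default grids (SVM C/kernel, tree depth/leaf size, forest
size/depth, LDA shrinkage, k-NN neighbors/weights, all behind a
standardization step), scored by mean 10-fold stratified CV accuracy
(fold count reduced with a warning on small sets), ties to the first
configuration. Metrics: accuracy and specificity (TN-based, for the
normal class) from the confusion matrix with ICPP = 1 positive;
precision/recall/F1 computed per class and averaged with true-class-count
weights — all as percentages, printed to two decimals.

## Conditional diffusion model

Forward process: linear β-schedule 0.001→0.02 over T = 200 steps,
ᾱ_t = Π(1−β_s), closed-form marginal f_t = √ᾱ_t f₀ + √(1−ᾱ_t) ε.
Segments are standardized per channel on training statistics; the
conditioning vector is [sinusoidal timestep embedding (32), class one-hot
(2), per-trial GLM β standardized on training statistics (10)].

The denoiser is a dense encoder–decoder over the flattened 10×60 segment
(hidden 256/128 at full scale, 128/64 in the desk profile) with SiLU
activations, an additive skip from the first encoder layer to the last
decoder layer, and the condition injected additively into every hidden
layer both through a learned 2-layer embedding and as the raw condition
vector (the latter guarantees the class bit reaches every layer regardless
of initialization). It is written directly in NumPy with hand-derived
backpropagation (verified against finite differences) and a hand-written
AdamW (lr 0.001, weight decay 0.01 on weight matrices), so training is
bit-reproducible from a seed.

Two deliberate departures from the textbook ε-objective, both forced by
this architecture and verified experimentally:

1. **Clean-signal parameterization.** The network predicts f̂₀ and the
   sampler computes ε̂ = (f_t − √ᾱ_t f̂₀)/√(1−ᾱ_t). A bottlenecked dense
   network cannot represent the near-identity map that direct ε-prediction
   requires (sampling collapsed to the marginal mean), whereas f₀ is
   low-rank. The training loss is the MSE on f₀, uniform over timesteps —
   exactly the SNR-reweighted ε MSE; the unweighted ε objective, written
   in f₀ space, has a weight that diverges at t → 1 and drowns the
   high-noise steps where the conditioning carries all the information.
2. **Classifier-free guidance.** During training the class/β condition is
   nulled with probability 0.15; at sampling the prediction is
   f̂₀ = f̂₀(null) + w·(f̂₀(cond) − f̂₀(null)) with w = 3. Without guidance
   conditional fidelity was initialization-dependent (class-mixed samples
   on some seeds); with it, toy class-conditional means are recovered
   within 0.3 across every seed tested.

Sampling is DDPM-ancestral with σ_t² = β_t and a deterministic final step.
Augmentation trains on real training segments only, generates as many
synthetic segments as there are real ones with matching class
proportions, flags them, and asserts the test set is disjoint from the
training keys. β conditioning for synthetic samples is resampled from the
real training β-vectors of the target class (per-trial conditioning keeps
the shapes aligned with segments).

Note that ᾱ_200 ≈ 0.121 under this schedule, so the forward process does
not fully whiten the data and the N(0, 1) sampling prior is an
approximation; the conditioning (with guidance) compensates in practice.

## Problem sizes and profiles

The desk-scale defaults — cohorts of 20–60 subjects, diffusion training
of 500–600 epochs on the 128/64-wide network, 10-seed replications for
calibration properties, 50-cohort replications for FDR and pair-recovery
checks, 500 replicates for CI coverage — are chosen so the whole suite
runs on a single CPU in a few minutes while keeping every Monte-Carlo
tolerance at ≥ 3 standard errors. The full-scale training configuration
(500 epochs, batch 64, hidden 256/128) is the `TrainConfig()` default.

## Known limitations

- The generator's noise is channel-independent; FDR calibration under
  spatially correlated noise is untested.
- MBLL recovery is mean-referenced (I₀ = temporal mean), so absolute
  concentration offsets are unidentifiable by construction.
- TDDR after a 0.1 Hz low-pass can only repair what the filter leaves;
  motion spikes are mostly attenuated by the filter itself in the default
  order.
- The diffusion model's sample quality at ~50 training trials is
  sufficient for the augmentation protocol's "does not degrade
  specificity" property, not for distributional fidelity claims.
- Classifier accuracies on synthetic cohorts depend on the planted
  effect sizes and should not be read as clinical performance estimates.
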