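# Methods

## Problem and overall design

`prealpha` implements a quantitative-EEG classifier that discriminates
dementia with Lewy bodies (DLB) from Alzheimer's disease (AD) using a
150-second eyes-closed resting EEG from the 19-electrode 10-20 montage,
plus the subject's age and gender. The discriminating physiology is the
posterior dominant rhythm: in AD it remains near alpha (~9 Hz) while in
DLB it slows into the "pre-alpha" range (~5.6-7.9 Hz), wanders more in
frequency, and is accompanied by more diffuse slow (1-4 Hz) activity.
Rather than encoding these contrasts as hand-picked band powers, the
pipeline feeds the classifier the complete second-order spectral
structure of the recording and lets supervised dimension reduction find
the discriminative directions.

The pipeline, end to end:

1. **Reference and filter.** Channels are re-referenced to the common
   average and band-passed 0.1-70 Hz with an order-8 Butterworth filter
   (8 poles per band edge). Application is zero-phase
   (forward-backward), so the effective magnitude response is the
   squared 16th-order band-pass; this preserves cross-channel phase
   relations, on which the covariance features depend. A single-pass
   mode is available by configuration.
2. **Epoch and segment.** A 150-s epoch is cut into 2-s windows stepped
   by 1 s: 149 overlapping segments. The method is undefined below
   150 s and raises rather than degrade silently.
3. **Spectra.** Each 2-s segment is Fourier transformed at its native
   0.5 Hz bin spacing (rectangular window, no zero padding); bins
   0.5-45 Hz give 90 complex coefficients sigma_cij per channel c and
   segment i. Coefficients are scaled 1/N so magnitudes are
   sampling-rate invariant.
4. **Spectral covariances.** For each of the 190 unordered channel
   pairs (19 auto + 171 cross) the full-spectral-resolution covariance
   chi_ckij = sigma_cij * conj(sigma_kij) is formed per segment. Auto
   pairs are the power spectra; their imaginary slots are kept as
   structural zeros so the feature book-keeping (190 x 90 x 2 = 34,200
   = 3,420 auto + 30,780 cross) is explicit.
5. **Robust aggregation.** Real and imaginary parts are aggregated
   across the 149 segments with the marginal median (20%-trimmed mean
   and plain mean available). The median's 50% breakdown point is what
   makes the pipeline tolerant of blink/EMG/ECG-contaminated segments
   without explicit artefact rejection: a minority of corrupted
   segments is simply outvoted.
6. **Per-pair PCA with AUC selection.** Each pair's 180-dim block
   (90 frequencies x re/im) is mean-centered across training subjects
   and decomposed by PCA (covariance PCA, no variance scaling — the
   downstream standardization absorbs scale). Every component is scored
   by the area under the ROC curve of its subject scores against the
   DLB/AD labels, folded to max(A, 1-A) because component orientation
   is arbitrary; ties break by explained-variance order. The two
   best-AUC components per pair are retained: 380 core features. A
   recording's core feature C_pa is the median across segments of the
   inner product between its centered per-segment block and the
   retained loading (first-two-by-variance selection is available by
   configuration).
7. **Classifier and index.** A genetic algorithm searches binary masks
   over the 380 features; fitness is the pooled out-of-fold AUC of a
   linear SVM (stratified 5-fold CV) on the masked features plus age A
   and A^2, minus a parsimony penalty lambda_p * |mask|/380. The SVM is
   fitted on standardized columns and its coefficients are
   de-standardized, so the index

       I_raw = sum_pa C_pa beta_pa + beta1A*A + beta2A*A^2 + rho

   reproduces the decision function exactly. The raw index is then
   rescaled: I = (I_raw - c*)/s_AD, where c* is the training cutoff
   maximizing Youden's J and s_AD is the standard deviation of the AD
   training cohort's raw indices. A recording is classified DLB iff
   I >= 0; one index unit is one AD-cohort standard deviation. Models
   are trained separately for men and women; a stratum with fewer than
   4 subjects per class falls back to a pooled model with a warning.

## Tunable parameters

| Parameter | Default | Notes |
|---|---|---|
| filter band / order | 0.1-70 Hz, order 8 | zero-phase by default |
| epoch / segment / step | 150 s / 2 s / 1 s | 149 segments |
| frequency bins | 0.5-45 Hz at 0.5 Hz | 90 bins |
| robust estimator | marginal median | `trimmed_mean` (20%), `mean` |
| components per pair | 2, by folded AUC | `variance` selection optional |
| SVM regularization C | 1.0 | on standardized columns |
| GA | pop 50, gen 100, uniform crossover 0.5, mutation 0.01/bit, elitism 2, tournament 3 | fully seeded |
| GA fitness | 5-fold CV-AUC − 0.01·maskfrac | |
| cutoff criterion | Youden's J | ties to the class-median midpoint |
| CI level | 95%, Clopper-Pearson | exact binomial |

## Statistical notes

Sensitivity, specificity and accuracy use DLB as the positive class.
Confidence intervals are exact binomial (Clopper-Pearson, beta-quantile
form); this choice reproduces standard published interval tables where
approximate (Wilson/Wald) intervals do not. The Fisher exact test uses
the two-sided "sum of no-more-probable tables" convention. ROC AUC is
the Mann-Whitney form with ties counting one half. Exact binomial power
uses the smallest critical count k* with P(X >= k* | p0) <= alpha and
reports P(X >= k* | p1).

## Synthetic cohorts

No public EEG of this kind is deposited, so the package ships a seeded
simulator whose defaults encode the qEEG contrasts above:

* AD-like: dominant frequency ~ N(9.0, 0.5) Hz (clipped 7-11),
  frequency-variability 0.3 Hz, slow-gain 1.0.
* DLB-like at full separation: dominant frequency ~ N(6.8, 0.6) clipped
  to the pre-alpha band [5.6, 7.9] Hz, variability 0.8 Hz, slow-gain
  1.8.
* A single knob lambda in [0, 1] linearly interpolates the DLB-like
  parameters toward the AD-like ones; lambda = 0 makes the groups
  generatively identical (the null condition).
* Each channel: posterior-weighted narrowband rhythm whose
  instantaneous frequency follows a reflected random walk, diffuse
  1-4 Hz noise scaled by the slow gain, pink (1/f) channel noise plus a
  shared pink source mixed at gain 0.3 (volume conduction, so cross
  covariances are informative), and optional blink/EMG artefacts at a
  configurable events/min rate. Amplitudes are microvolt-scale (rhythm
  15 uV peak posterior, pink 8 uV RMS, slow 4 uV RMS x gain).
* Ages ~ N(76.5, 6.0) truncated to [50, 90]; gender Bernoulli(0.5);
  cohorts enrolled 1:1.

The amplitude and noise values are the package's own choices (the
clinical literature gives qualitative contrasts, not generative
parameters); they are exposed in `prealpha.synthetic` and were fixed
once at values that put the simulated posterior rhythm and background
in a realistic microvolt range.

What the simulator does **not** model: genuine nonstationarity (drowsiness,
state shifts), medication effects on EEG rhythms, volume-conduction
geometry beyond a single shared source, non-Gaussian artefact
morphology, inter-site amplifier differences. Passing the synthetic
studies therefore demonstrates that the pipeline recovers the encoded
group contrast and stays calibrated under the null — not that it
attains any particular accuracy on clinical recordings, and the
proprietary coefficients of the clinically validated instrument are not
reproduced here.

## Simulation studies and problem sizes

`prealpha.experiments.heldout_run` trains on one synthetic cohort and
evaluates on an independent one. The shipped studies use 40 + 40
training and 20 + 20 test subjects per run, ten seeds, at lambda = 1
(signal recovery: held-out AUC and threshold accuracy) and lambda = 0
(null calibration: held-out AUC near 0.5). For these studies the GA is
run at population 20 / 10 generations: with the strong synthetic
contrast the CV-AUC fitness saturates quickly, and the shorter search
keeps a ten-seed study tractable on a single CPU; the library default
(50/100) remains appropriate for weaker, real-world contrasts.

## Numerical choices and degenerate inputs

* The spectral chain (DFT coefficients onward) runs in single
  precision: it halves the memory and time of the 149 x 190 x 90
  covariance tensors, and 32-bit resolution (~1e-7 relative) is
  negligible next to across-segment scatter. PCA loadings and all
  classifier algebra are double precision.
* Auto-covariance imaginary parts are forced to exactly zero (fused
  multiply-add contraction otherwise leaves ~1e-9 residues).
* The DFT uses the e^{-i w t} kernel (numpy convention); a pure delay
  tau of channel k multiplies chi_ck by e^{+i w tau}. The sign of
  cross-spectral phases flips under the opposite kernel convention.
* Median vs mean aggregation: for noise-dominated spectral power the
  across-segment distribution is exponential, so the median is ln 2 of
  the mean — a deliberate, benign bias (monotone per-feature rescaling)
  that standardization absorbs. For sustained rhythms the per-segment
  covariance is nearly constant and the two estimators coincide.
* Zero-variance feature blocks yield components only for the non-zero
  subspace; pairs with fewer than two valid components are padded with
  zero loadings (logged), producing structurally zero core features.
* Zero-variance design columns are dropped from SVM standardization
  (coefficient 0). Calibration raises if the AD cohort's raw indices
  have zero spread.
* All randomness (simulator, GA, CV folds) derives from explicit seeds
  via `numpy` seed sequences; identical configuration and seed give
  bit-identical models.
* The EDF writer quantizes to a symmetric 16-bit digital range
  (+/-32767) over a per-channel symmetric physical range, so zero maps
  to zero and round-trip error is below half an LSB; it requires
  whole-second recordings at an integer sampling rate.

## Known limitations

* The trained coefficients of the original clinical instrument were
  never published; this package reproduces the *method*, trainable on
  user or synthetic cohorts, not that instrument's weights or its
  real-cohort operating characteristics.
* Epoch selection takes the first 150 s by default; the clinical
  procedure used technician-selected artefact-free epochs. An optional
  amplitude-threshold scan is not implemented beyond the robust
  aggregation defense.
* The GA optimizes a noisy CV objective; masks are seed-dependent even
  when the resulting indices agree closely.
* `read_edf` trusts the channel-synonym table; exotic montage labels
  not covered by it surface as montage errors rather than guesses.
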