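# Methods

`mvpakit` implements a time-resolved multivariate pattern analysis (MVPA)
workflow for evoked M/EEG epochs, together with a mutual-information (MI)
procedure that quantifies how much information each preprocessing step
discards. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not show about real recordings.

## The decoding model

The unit of analysis is an epoch set: `trials × channels × timepoints` with
binary condition labels (congruent/incongruent) and pair identifiers tying
the two conditions of one stimulus (sentence body) together. Decoding is
*time-resolved*: at every timepoint `t`, the channel vector `x_t ∈ R^C` is
the feature vector, and a classifier is trained to predict the condition
label under stratified k-fold cross-validation. The fold-mean held-out
accuracy as a function of peristimulus time is the decoding curve; accuracy
significantly above chance (0.5 for balanced binary labels) at time `t` is
evidence that the spatial activity pattern at `t` carries condition
information.

The default pipeline is: resample 1000 Hz epochs to 200 Hz (anti-aliased
polyphase FIR, zero-phase), single-trial analysis (no pseudo-trial
averaging, no sliding window), per-fold standardization, per-fold PCA
retaining 99% of the training variance, LDA (SVD solver, no priors, no
shrinkage, tolerance 1e-4), stratified 10-fold CV. Alternatives exposed as
config axes: resampling to 200/100/50 Hz; sliding windows of 5/10/20 ms
with a step of 0.6 window lengths; pseudo-trial averaging over groups of
2/4/6; PCA vs univariate channel selection vs no reduction; ridge
regression (SAG solver, alpha = 1, sign decision with ties to class 0) and
sigmoid-kernel SVM (tolerance 1e-4, shrinking, no class weights, gamma =
1/(n_features · Var), coef0 = 0 — kernel coefficients are not standardized
in the literature for this use, so the scikit-learn defaults are recorded
in the config); k ∈ {2, 5, 10} folds; MEG, EEG, or fused modalities.

### Leakage discipline

Standardization and PCA are fit on the training rows of each fold only and
applied to both partitions; perturbing test rows cannot change the learned
transforms. Class balancing (seeded downsampling of the majority class) and
pseudo-trial averaging happen before CV splitting: averaging is within
condition, so it cannot leak labels, and pseudo-trials are the natural CV
unit. Univariate channel selection is computed once per subject on the
conditioned epochs (not per fold), mirroring the participant-level
selection it models; this is a supervised step outside the CV loop and is
therefore reported as a *reduction choice*, not an unbiased accuracy
estimate — the comparison across reduction choices is the point, and all
choices share the same CV protocol.

### Channel selection

Per channel, the statistic is the paired t of the condition difference of
the per-trial mean amplitude over the 200–600 ms window (one test per
channel; pooling per-timepoint tests would multiply the correction burden
without changing the ranking). The null is built by sign-flipping the
paired differences (label shuffling in the unpaired fallback), 1000
resamples by default, p-values by the add-one rule
`(1 + #{|t*| ≥ |t|}) / (1 + B)`, and Benjamini–Hochberg step-up control at
q = 0.05 across channels. A parametric paired-t fallback is available by
flag. An empty selection falls back to all channels with a warning.

### Group inference

With six subjects, normal approximations to the Wilcoxon signed-rank null
are invalid, so the one-sided (greater) test against chance is computed
exactly: zeros dropped, midranks for ties, and the null distribution of the
positive rank sum built by subset-sum counting over all 2^n sign
assignments (n ≤ 25; a tie-corrected, continuity-corrected normal
approximation above that). The smallest attainable p at n = 6 is 1/64, and
the attainable level closest to 0.05 from below is 3/64 ≈ 0.0469 — the test
is intrinsically conservative at this sample size. **No correction is
applied across timepoints**: significance discs on decoding curves are
per-timepoint statements, a deliberate caveat inherited from the analysis
style this package reproduces; BH control is reserved for the channel
dimension. The modality-difference test (e.g. fused vs MEG) applies the
same one-sided exact test to per-subject curve differences against zero;
one-sided was chosen because the question posed is "higher than", not
"different from".

## The mutual-information procedure

To measure what a reduction operation discards, observations are paired
through the operation: the observation unit is the per-(trial, timepoint)
channel vector (optionally subsampled to a 20 000-row cap), the benchmark
row is the full channel vector, and the operated row is the representation
the operation assigns to that same sample — the PCA/masked vector (channel
dimension), the pseudo-trial vector of the group containing the trial
(trial dimension), or the vector at the decimated timepoint / nearest
window centre containing the sample (temporal dimension). Then, per
repeat:

1. fit Gaussian mixtures to the benchmark rows, the operated rows, and
   their joint concatenation, choosing the component count (1–10) by AIC;
   full covariances with 1e-6 ridge regularization, diagonal when there are
   fewer than 5·d observations;
2. draw `n_mc` samples (default 10 000) from the joint mixture;
3. estimate MI on the sampled pairs with the Kraskov–Stögbauer–Grassberger
   k-nearest-neighbour estimator (k = 3, Chebyshev metric, strict-inequality
   neighbour counts); the mixture log-density ratio
   `E[log p_joint − log p_x − log p_y]` over the same samples is retained
   as a diagnostic.

The final MI is the repeat mean (default 10 repeats), clipped at zero, in
nats. Fitting a *joint* mixture is what makes "sample from the fitted
distributions, then estimate MI on the samples" well defined: sampling the
two marginal fits independently would destroy the dependence being
measured. The kNN estimate is the headline number because the density-ratio
estimate inherits any mixture misfit twice.

A closed-form oracle, `MI = ½(ln det Σx + ln det Σy − ln det Σ)` for
jointly Gaussian pairs, anchors the estimator's tests: at 5000 observations
the estimate lands within ±0.05 nats of `−½ ln(1−ρ²)` for 1-D pairs at
ρ ∈ {0, 0.5, 0.9} and within 10% of the log-determinant form for a 3-D
linear-Gaussian map. Downstream, Pearson correlation (two-sided p from
`t = r√((n−2)/(1−r²))` on n−2 df) relates per-subject MI to peak-accuracy
differences, and Welch two-sided t-tests compare MI across the three
reduction dimensions.

## The synthetic cohort

Real N400 recordings of the kind this pipeline targets are not publicly
distributable, so the benchmark is synthetic and generative:

* **Design.** 196 trials per subject (192 in the calibration runs so all
  counts divide evenly), one congruent and one incongruent presentation per
  sentence body (`pair_ids`), pseudo-random order, optional imbalance knob.
  Epochs span −200…1000 ms at 1000 Hz; 40 magnetometer-scale (1e-13 T) and
  64 electrode-scale (1e-6 V) channels.
* **Signal.** Two shared components common to both conditions (latency
  100/250 ms, widths 80/120 ms, amplitudes 1.5/1.0 in noise-SD units)
  emulating early auditory responses, plus a condition-difference component:
  a Hann-tapered bump (smooth, compactly supported; any smooth unimodal
  waveform would do) centred at 400 ms with 150 ms support, projected onto
  a fixed random spatial pattern over half the channels. Default amplitude
  0.08 (noise-SD units per active channel) puts a single subject's peak
  decoding accuracy near 0.7–0.75 — the realistic regime for evoked
  decoding, well away from both chance and ceiling.
* **Subjects.** Multiplicative amplitude scatter (SD 0.2) and latency
  jitter (SD 20 ms) per subject. Random streams are split per
  (seed, subject, role), so enlarging a cohort never changes earlier
  subjects' data.
* **Noise.** AR(1) in time (coefficient 0.9, exact stationary
  initialization) mixed across channels through the Cholesky factor of a
  squared-exponential kernel over a 1-D channel ordering (length 5
  channels, unit marginal variance) — the cheapest structure that makes
  PCA non-trivial — plus white sensor noise (SD 0.5).
* **Null mode.** `effect_amplitude = 0` removes every label-dependent term,
  making labels and data independent by construction; this is the ground
  truth for the chance and type-I calibrations.

What the generator does *not* emulate: realistic sensor geometry or forward
fields, blink/cardiac artifacts, non-stationary noise, 1/f spectra beyond
AR(1), or cross-modality correlated noise (MEG and EEG noise streams are
independent, while real modalities share brain noise). Passing calibrations
on this cohort therefore demonstrates the *statistical machinery* —
leakage-free CV, exact test calibration, estimator consistency — not
performance on any particular real dataset.

## Numerical choices

* PCA keeps the smallest m with cumulative explained variance ≥ threshold
  (boundary inclusive, 1e-12 slack against rounding); threshold 1.0 keeps
  the full training rank `min(n−1, C)`. Principal axes are computed from
  the feature-space Gram matrix — algebraically the thin-SVD solution,
  cross-checked against scikit-learn's PCA in the tests.
* The hot-loop LDA reimplements scikit-learn's SVD solver for two classes
  (tolerance-truncated within-class whitening; the between-class step is
  rank one analytically); predictions are asserted equal to scikit-learn's
  over random, rank-deficient and constant-feature inputs. This exists
  purely because ~10^6 per-fold fits are run in the calibration studies.
* Sliding windows use an integer step `round(0.6·L)` anchored at the epoch
  start, with window-centre timestamps (centres minimize latency bias);
  windows extending past the epoch are dropped.
* Trial-averaging leftovers (count < group size) are dropped rather than
  pooled, keeping pseudo-trial noise variance homogeneous; the grouping is
  seeded and within condition (whether to respect sentence-body pairing is
  unspecified in the source analysis style; randomization is recorded).
* Epoch flagging standardizes per channel over all trials and timepoints
  and rejects trials whose max |z| exceeds a data-dependent threshold; no
  default threshold is applied to synthetic data (it contains no
  artifacts).
* The z-scored permutation p lower bound is 1/(1+B); B defaults to 1000.
* Degenerate inputs: all-zero signed-rank differences give p = 1 with a
  warning; zero-variance operated data give MI = 0 with a warning; an empty
  channel selection falls back to all channels.

## Calibration studies and problem sizes

Two calibration quantities are recomputed from scratch by
`scripts/acceptance.py` (and asserted in the test suite):

1. **Chance calibration** — 20 null cohorts × 2 subjects (192 trials, 40
   channels, 1000→200 Hz), default pipeline; the grand mean accuracy over
   timepoints, subjects and replicates must lie in 0.5 ± 0.02. Two subjects
   per replicate cohort keep the full recomputation in the few-minute range
   on one CPU; the estimate's Monte-Carlo error is far below the band
   either way.
2. **Type-I error** — 200 null cohorts × 6 subjects on a 50-timepoint grid
   (native 50 Hz over −0.2…0.8 s, 64 trials); the fraction of significant
   (timepoint, cohort) pairs must not exceed 0.05 (plus two binomial
   standard errors); the exact test's attainable level at n = 6 is
   3/64 ≈ 0.0469. The null calibration is insensitive to trial count and
   grid, which were sized for the same reason.

## Known limitations

* Per-timepoint group inference is uncorrected across time (see above).
* The univariate selector is participant-level, outside the CV loop.
* The MI estimate inherits the GMM's bias where the data are far from a
  mixture of Gaussians; the KSG estimator is itself biased upward at small
  sample sizes and in high dimensions (the 3-D oracle bound of 10% reflects
  this).
* Binary labels only; no temporal-generalization matrices; no source-space
  analysis.
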