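# Methods

This note documents the models, parameter choices and numerical conventions
behind `msdeeg`, and what the synthetic cohorts do and do not establish.

## Signal model and preprocessing

Input recordings are assumed referenced (ear reference) and expressed in
microvolts; no re-referencing is performed. The cleaning chain is, in order:

1. **Band limiting.** Butterworth IIR filters of order 4: high-pass at
   0.5 Hz (drift/DC), low-pass at 45 Hz, band-stop 48–52 Hz (power line).
   The low-pass default of 45 Hz keeps the delta–beta range that carries
   stress-related activity while excluding line noise and most EMG; any
   cutoff at or above Nyquist is rejected. All filters run forward–reverse
   (`sosfiltfilt`), so the chain is zero-phase: a band-interior sinusoid
   emerges with zero sample lag, and spectral features are not biased by
   group delay. Edge transients are handled by the forward–reverse scheme's
   reflect padding (three times the effective filter order).
2. **Wavelet denoising.** Five-level decomposition with the Symlets wavelet
   of 4 vanishing moments (`sym4`), universal threshold
   `t = sigma * sqrt(2 ln n)` with soft shrinkage. The noise scale `sigma`
   is estimated from the median absolute deviation of the *finest* detail
   level and applied to all levels. An optional per-level estimate exists
   but is not the default: band-limited rhythms (alpha, beta) dominate the
   mid-level detail coefficients, so a per-level MAD measures the signal
   itself and the universal threshold then shrinks those rhythms toward
   zero — on our synthetic cohorts it erased most of the class effect. With
   white, finest-level noise the default removes broadband noise while
   retaining oscillatory structure.
3. **Savitzky–Golay smoothing.** Window 11 samples, polynomial order 3 —
   mild smoothing at 500 Hz that reproduces polynomials up to cubic exactly
   and leaves the analysis bands essentially untouched.

Every stage maps channels × time to the same shape, is deterministic, and
can be disabled independently.

## Segmentation

Continuous recordings are preprocessed first, then cut into 4 s windows
advanced by 1 s (trial count `floor((L−W)/S) + 1`; the last partial window
is dropped, never padded). Four-second windows are short enough that EEG is
approximately stationary within a trial while giving 0.25 Hz spectral
resolution. Note that adjacent trials share 75% of their samples; the
consequences for trial-wise cross-validation are discussed below.

## Features

All features are computed per channel per trial; nothing mixes channels, so
restricting a feature matrix to a channel subset is exactly equivalent to
re-extracting features from the restricted trials (this identity is tested).

**Spectrum.** A single unwindowed periodogram of the 4 s trial (Welch
averaging would trade variance for resolution; the plain periodogram is the
default to keep the features' statistical definition simple). The
phase-excluded power spectrum `P_k = |X_k|²/N` is stored folded onto the
one-sided grid (interior bins doubled), so `sum(P_k)` equals the time-domain
energy `sum(x_i²)` by Parseval's theorem; this identity is enforced to 1e−6
relative in the tests.

**Frequency features (set 1, 5 per channel).**

- `MDF`: the first grid frequency at which the cumulative PSD reaches half
  its total. No interpolation — the estimate is quantised to the 0.25 Hz
  grid, which is deliberate: it makes the feature exactly reproducible and
  the brute-force oracle trivial.
- `MFMD`: the same construction applied to the amplitude spectrum.
- Root spectral moments `m_r = sqrt(Σ_k k^r P_k)`, r = 0, 2, 4. The moment
  index `k` is the one-sided frequency-bin index, not Hz: moments in bin
  units are sampling-rate independent for a fixed window length, and the
  square root puts `m0` on the amplitude scale (`m0 = sqrt(Σ x²)`). A
  configuration flag disables the root; the choice is a monotone rescaling
  and does not affect rank-based classifiers.

**Time features (set 2, 7 per channel).** RMS amplitude and the six
coefficients of an AR(6) model in the prediction convention
`x_i ≈ Σ_d a_d x_{i−d}`. The default estimator is Yule–Walker on biased
(1/N) autocovariances — solved as a batch of 6×6 Toeplitz systems across
all trials and channels at once for speed — with Burg's method available by
option. Simulate-and-refit recovery of known stable AR(6) coefficients at
n = 10⁵ is within ±0.05 per coefficient (tested; typical error is below
0.01), and the batched solver agrees with `statsmodels`' reference
implementation to 1e−8. Constant (zero-variance) channels get all-zero
coefficients and a warning rather than an exception.

Set 3 concatenates sets 1 and 2 per channel: 12 features/channel, 228 on
the 19-channel montage, 24 on Fp1+Fp2.

## Reduction and selection

Features are standardized (training-fold mean/variance) before PCA and
before distance-based classifiers; with mixed units (Hz, µV, dimensionless
AR coefficients) raw covariance would be dominated by the large-magnitude
moments. The sequential forward search scans k = 1 … max_k eigenvalue-ordered
principal components and reports cross-validated accuracy per k, choosing
the smallest k at the maximum. Scaler and PCA are refit inside each
training fold (the leading k components of a fitted PCA do not depend on k,
so one fit per fold serves the whole scan); a `pca_scope="global"` option
reproduces the simpler whole-data fit for comparison, at the cost of mild
leakage.

Electrode experiments evaluate the five scalp sites (frontal = Fp1, Fp2,
F3, F4, Fz, F7, F8; temporal = T3, T4, T5, T6; central = C3, C4, Cz;
parietal = P3, P4, Pz; occipital = O1, O2), each frontal electrode alone,
and the fusions Fp1+Fp2, Fp1+F8, Fp1+F7+F8. Fold plans are identical (same
seed) across subsets so comparisons are paired.

## Classification and metrics

The classifier contract wraps scikit-learn estimators: LDA, linear SVM
(C = 1), cubic SVM (polynomial kernel, degree 3), 1-NN with Euclidean
distance, and a random forest (100 trees, sqrt(p) features per split,
seeded). The positive class is the stress state (detection) or the
high-stress group (levels); the stress-level task uses task-state trials
only, since rest-state activity does not separate the groups.

Validation is stratified 5-fold over trials or leave-one-subject-out (LOSO;
one fold per subject, so test subjects contribute no training trials).
Metric point values are means over folds with Student-t 95% intervals
(a percentile bootstrap is available); metrics of the pooled confusion
table are reported alongside and used for the reliability gate, being more
stable than fold means for rare-error regimes. The t-interval over fold
accuracies can exceed [0, 100]% near the ceiling; it is reported unclipped
to keep it honest about its construction.

Degenerate confusion cells: the DOR of an error-free table is reported as
infinite and flagged (and passes the ≥ 100 gate); with any other zero cell
a 0.5 continuity correction is applied to all cells and flagged. An MCC
with zero denominator is reported as 0.

## Synthetic cohorts

The generator emulates the study protocol: per subject one rest recording
(default 180 s) and one task recording (60 s), 19 channels at 500 Hz, with
26 low-stress and 10 high-stress subjects by default (an imbalanced cohort,
matching the discussion of stress-level class imbalance). Each channel is a
sum of unit-RMS Gaussian noise band-passed into delta (0.5–4 Hz, 20 µV),
theta (4–8, 10 µV), alpha (8–13, 15 µV) and beta (13–30 Hz, 8 µV), plus
white sensor noise (3 µV) and a 50 Hz line component (2 µV, random phase
per channel per recording).

Stress is modelled as multiplicative band-power changes on the seven
frontal channels: during the task, beta ×4.5, alpha ×0.3, theta ×0.6,
delta ×0.5 — a frontal desynchronization signature (slow-band suppression
with fast-band enhancement); high-stress subjects additionally show
beta ×2.0 and theta ×1.6 during the task. These magnitudes were chosen once
so that the cohort sits in the regime the method targets: near-ceiling
trial-wise accuracy on frontal channels, clearly degraded accuracy from
posterior sites, and a marked LOSO drop for the stress-level task. Each
subject carries a log-normal overall gain (sd 0.10) and per-band power
jitter (sd 0.15), shared between their rest and task recordings, which is
what makes leave-one-subject-out genuinely harder than trial-wise
cross-validation. Everything derives from one seed; the same seed
reproduces a cohort bit-for-bit.

**What the generator does not emulate:** 1/f background structure beyond
the four bands, ocular/muscle artifacts, electrode drift or pops,
non-stationarity within a recording, volume-conduction correlations between
channels, and any physiological forward model. Passing tests on these
cohorts therefore demonstrate the pipeline's correctness and its behaviour
under known, controllable effects — not that the chosen features are
sufficient for real recordings.

**Trial-wise cross-validation is optimistic by construction.** Windows of
one continuous recording share that recording's realized mean band power
(and adjacent windows share 75% of their samples), so a 1-NN classifier
under trial-wise 5-fold stays mildly above chance even on a cohort with the
stress effects switched off (~73% observed on a balanced null cohort). This
is recording-level leakage, not signal. The package's null checks are
therefore posed where the null is well-defined: leave-one-subject-out on
the zero-effect cohort (~54%, within binomial chance bounds) and
label-permutation under 5-fold (~50%). The same mechanism is why reported
trial-wise accuracies near 100% should be read together with the LOSO
results.

## Problem sizes and defaults used in the shipped checks

The test suite and `scripts/acceptance.py` run the full default cohort
(36 subjects, 8424 trials × 228 features) for the end-to-end checks —
about 1.5 minutes of feature extraction on one CPU — and smaller cohorts
(8–10 subjects, 20–60 s recordings) for stage-level tests. The
principal-component search in the acceptance script scans k = 1…20 on the
Fp1+Fp2 feature space (24 features) rather than all 228, which is where the
minimal-electrode system would use it.

## Known limitations

- EDF is read (via `mne`); there is no EDF writer, so generated cohorts are
  stored as CSV + YAML manifest.
- Only binary tasks (stress vs. rest; low vs. high) are supported.
- No artifact-specific removal (ICA, regression); the cleaning chain
  assumes visually screened input.
- Confidence intervals summarise fold dispersion, not subject-level
  uncertainty; with 5 folds they are wide and should not be over-read.
- The spectral features use the raw periodogram; for windows much longer
  than 4 s, enabling Welch averaging is advisable.
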