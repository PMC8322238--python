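# Methods

This note documents the models, numerical choices, and validation logic
behind `musictrf`, in the spirit of a methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic
validation does and does not establish.

## Tonal features

**Chromagram.** Each analysis window is Fourier-transformed and the
squared-magnitude spectrum between a 30 Hz pitch floor and a 3 kHz
ceiling is folded onto 12 equal-temperament pitch classes (A4 = 440 Hz
reference; each bin is assigned to its nearest pitch class). The window
must span at least two periods of the pitch floor; shorter windows raise
an error naming the minimum length, and terminal event windows below the
minimum are dropped from the sparse encoding rather than fabricated.
This FFT-folding front end keeps the chroma content of the synthetic
sine-triad stimuli analytically predictable; it omits the
spectrogram/cochleogram smoothing that MIR toolboxes apply, which mainly
broadens energy across neighboring pitch classes.

**Key strength, clarity.** The Krumhansl–Kessler probe-tone profiles
(major: 6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66,
2.29, 2.88; minor: 6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75,
3.98, 2.69, 3.34, 3.17) are rotated to all 24 keys; key strength is the
Pearson correlation of a chroma vector against each, ordered 12 major
then 12 minor. Key clarity is the maximum entry; ties resolve to the
lowest key index (and are logged). A zero-variance chroma (silence, flat
energy) leaves the correlation undefined; such events propagate as
missing and are dropped from regressors, never imputed.

**Tonal stability.** s(t) = 1 − θ/π with θ the angle between v(t) and
the cumulative mean v̄(t−1) = Σᵢ₌₁^{t−1} v(i)/(t−1). The angle is
evaluated as 2·atan2(‖û−v̂‖, ‖û+v̂‖) on unit-normalized vectors —
algebraically identical to arccos of the clamped normalized dot product,
but exact at the parallel/antiparallel extremes where arccos loses half
its floating-point precision. The first valid event has no prior
context; v̄(0) := v(1) by convention, so s(1) = 1 — a neutral
initialization that avoids spurious instability at stimulus onset.

**Sparse encoding.** Tonal features are computed on beat-spanning (or
measure-spanning) windows [eᵢ, eᵢ₊₁), the last window extending to the
audio end, and placed as impulses at event onsets — the same encoding
used for word-level predictors in naturalistic speech TRF studies. A
fixed-window mode (`window_s`) is available as a configuration option.

**Key-space geometry.** Correlating each of the 24 ideal profiles
against all 24 gives 24 key-strength vectors in R²⁴; centered PCA of
this stack yields the familiar circle-of-fifths geometry, with C major
and F♯ major projecting to opposite sides of the origin. With these
profiles the first two components carry 78.1% of the total variance
(83.6% for the 12-major-key subset); figures near 65% reported in the
literature for this construction likely reflect a smoothed chromagram
front end or stimulus-frame (rather than ideal-profile) key-strength
vectors, neither of which is recoverable from published descriptions.
Both variants are computed and reported by `scripts/acceptance.py`.

## Rhythmic features

Beats are unit impulse trains (1 at each beat sample). Meter splits
beats into strong/middle/weak accent tiers (4/4:
strong-weak-middle-weak; 3/4: strong-weak-weak); tiers encode accent
strength, not bar position, and partition the beat set. In 3/4 the
middle tier is an all-zero regressor, retained so model dimensionality
matches across time signatures; ridge regularization keeps the inert
column harmless. Onset→sample mapping rounds half away from zero — at
128 Hz the ±3.9 ms quantization is well inside TRF lag resolution.
Collisions (two events on one sample) keep a single impulse and are
logged. Annotations are assumed music-relative (cue beats precede the
epoch and are outside it).

## Envelope and surrogates

The broadband envelope is |analytic signal| of the audio, low-pass
filtered with a zero-phase FIR at 0.45 × the target rate (anti-aliasing
requires a low-pass; the filter is applied once, followed by a single
polyphase resampling step). Phase-randomized surrogates draw uniform
phases for the interior rFFT bins, keep DC and Nyquist fixed so the
output is exactly real, and preserve the amplitude spectrum bin-for-bin
(< 1e−10 relative deviation; mean and total power follow by Parseval).
Within one control repetition the same surrogate is reused for every
repeated trial of a stimulus; the 50-repetition control loop is fully
seeded and reproducible.

## TRF estimation

Lag indices run floor(tmin·fs)…ceil(tmax·fs) inclusive (−150…450 ms at
128 Hz → lags −20…58, i.e. 79 delays; positive lag = stimulus precedes
response). Rows whose lag window exceeds the trial are discarded, so a
trial of T samples contributes T − 78 rows under the default window.
Features and EEG are Z-scored per trial before lagging. The ridge
normal equations are solved by symmetric positive-definite (Cholesky)
factorization — never an explicit inverse; λ = 0 falls back to a
least-squares solve and raises on rank deficiency. For the λ grid the
implementation eigendecomposes the accumulated Gram matrix once and
evaluates all 21 penalties and all channels from the same basis.

Cross-validation is nested to avoid selection leakage: the outer loop
holds out one trial; an inner leave-one-out over the remaining trials
scores every λ per channel, λ is chosen per channel by the *mean* inner
accuracy (ties → smallest λ, i.e. least regularization consistent with
the optimum), the kernel is refit on all training trials at the chosen
λ, and the held-out trial is scored by Pearson r per channel. Fold
accuracies are averaged per channel (per-fold-then-average rather than
pooled). A global-λ option (`per_channel=False`) exists for comparison.
Degenerate held-out channels (constant response or prediction) yield
missing accuracies, recorded as NaN and ignored by the fold average.

## Model comparison

Families nest as env → env+beat → env+meter → env+meter+clarity /
env+meter+stability; the meter comparison tests env+meter against
env+beat, and the envelope comparison tests the observed envelope
against the surrogate-averaged accuracies. Because a nested addition can
only add explanatory power, the default test is one-sided (full >
reduced); a two-sided option forms positive and negative clusters at the
split alpha. Channels with paired-t p < 0.05 form connected clusters
over the adjacency graph (4-neighborhood for synthetic grids; a
distance-threshold constructor covers measured cap coordinates — the
appropriate template radius is a user decision exposed via
configuration). The cluster statistic is the summed t; the null is built
from independently sampled participant sign-flip assignments
("permutations with replacement" — duplicate assignments allowed),
default 10,000; cluster p = (1 + #{null max ≥ observed})/(n_perm + 1),
so the smallest attainable p is 1/(n_perm + 1). The cluster-forming
threshold affects sensitivity, not FWER validity. Cluster-mean accuracy
differences receive percentile bootstrap CIs over participants (default
10,000 resamples).

## Synthetic data

Audio is synthesized as sine-wave block triads of a scheduled key plan,
articulated on a metronomic grid with exponential decay — chroma ground
truth is analytic, so tonal features are verifiable in closed form. EEG
is generated from the model the analysis assumes: regressors convolved
with smooth random biphasic kernels on declared spatial supports, plus
Gaussian noise (optional AR(1), φ = 0.3, mimicking EEG autocorrelation)
scaled per channel to a target SNR, then Z-scored per trial. The
fixture bundle mirrors a familiar-melody listening study: 12 stimuli
(six 3/4, six 4/4; 104–213 BPM; 6.9–13.9 s), five repetitions (60
trials per participant), nine participants, 64 channels at 128 Hz.

The dissociation ground truth plants envelope kernels everywhere, a
uniform beat kernel on a central 3×3 patch, and an accent *contrast* on
a frontal band — tier kernels constrained to sum to zero across
strong/middle/weak with a shared gain pattern, so a uniform beat
regressor explains none of the frontal signal and the beat and meter
effects are spatially separable by construction. Without that
constraint a beat regressor (the sum of the tier trains) picks up the
mean tier response wherever meter is encoded, which is a real property
of the nested families, not a bug.

What the synthetic validation shows: the estimator recovers planted
kernels (median r > 0.9 at 6 dB SNR with 20 trials), the permutation
test controls FWER at its nominal level, and the comparison suite
separates spatially distinct encodings. What it does not show: robustness
to non-Gaussian artifacts, volume conduction, inter-participant kernel
variability, or correlated real-music feature covariation — real
recordings carry all of these, and null results on tonal features in
particular can reflect limited stimulus tonal variation rather than
absent encoding.

## Preprocessing

EEG is band-passed 1–8 Hz with a Hamming windowed-sinc FIR (length
⌈3.3·fs⌉ | 1, 1 Hz transition) applied zero-phase, polyphase-resampled
to 128 Hz, trimmed by 100 ms at music onset and offset, and Z-scored
per channel within the trial. Zero-phase application squares the
magnitude response, so single-pass attenuation figures double in
practice. An optional pre-cleaning hook accepts an externally computed
artifact-removal transform (e.g. ICA demixing supplied with a dataset);
artifact decomposition itself is out of scope.

## Problem sizes used in validation

The validation suite runs at demonstration scale chosen to exercise
every code path with comfortable statistical margins: kernel-recovery
at 16 channels, 64 Hz, 20 trials; FWER control with 200 null datasets ×
1,000 permutations on a 9-participant, 64-channel grid; the spatial
dissociation with 20 replicates of 9 participants × 6 trials (six
stimuli, lags 0–250 ms at 64 Hz). The defaults in `PipelineConfig`
(128 Hz, −150…450 ms, 10,000 permutations/resamples, 50 phase
randomizations) are the full-analysis settings.

## Known limitations

- A single λ is shared across feature sets within a model (no banded
  ridge with per-feature penalties).
- Clustering is over channels only, not channel × lag; no TFCE.
- The chromagram front end has no cochlear or spectrogram smoothing.
- The tonal-stability context is a single cumulative average; pieces
  with multiple shifting tonal centers would need a windowed or
  multi-center variant.
- Beat tracking and artifact decomposition are consumed as annotations /
  external transforms, never computed here.
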