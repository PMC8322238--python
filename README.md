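# musictrf

Linearized encoding analysis of **tonal and rhythmic hierarchy in
continuous-music EEG**: music-information-retrieval feature extraction,
ridge-regularized temporal response functions (TRFs), nested-model
comparison with cluster-based permutation inference, and a
phase-randomization control — plus a synthetic-data generator with planted
ground truth so the whole pipeline is testable end to end without any
external recordings.

## Who this is for

Auditory cognitive neuroscientists who want to ask, from EEG recorded
during natural music listening, *which* musical features — the acoustic
envelope, beats, metrical accents, or hierarchical tonal structure — are
encoded in ongoing cortical activity, and *where* on the scalp.

## The model

Per EEG channel, the encoding model is a lagged FIR regression

    y = Xβ + ε,        β̂(λ) = (XᵀX + λI)⁻¹ Xᵀy

where **X** stacks P stimulus features over D time lags (a Toeplitz
matrix; by default 79 delays spanning −150…450 ms at 128 Hz), rows whose
lag window would cross a trial edge are discarded (valid boundary
condition), and λ is selected per channel on a 21-point log grid
(2⁻¹⁰…2¹⁰) by nested leave-one-out cross-validation over trials.
Prediction accuracy is the Pearson correlation between the predicted and
observed held-out response.

Feature regressors:

- **envelope** — |Hilbert transform| of the audio, anti-alias low-pass
  filtered and resampled to the EEG rate;
- **beat** — unit impulses at annotated beat onsets;
- **meter** — three impulse trains splitting beats by accent strength
  (4/4: strong-weak-middle-weak; 3/4: strong-weak-weak);
- **key clarity** — the maximum of the 24-dimensional *key strength*
  vector (Pearson correlation of the window's chromagram against the
  Krumhansl–Kessler major/minor tonal-hierarchy profiles rotated to all
  24 keys), placed as an impulse at each beat/measure onset;
- **tonal stability** — the angular similarity
  s(t) = 1 − θ/π between the current key-strength vector v(t) and the
  cumulative mean v̄(t−1) of all preceding ones: 1 for a frame parallel
  to its tonal context, 0.5 for orthogonal, 0 for opposite.

Feature encoding is inferred by comparing nested model families
(env → env+beat → env+meter → env+meter+clarity / env+meter+stability):
per-channel paired t-values on accuracy differences are thresholded and
clustered over the channel adjacency graph, and each cluster's summed t
is referred to a Monte Carlo null of maximum cluster statistics built
from participant sign-flips, controlling the family-wise error rate. The
envelope itself is tested against phase-randomized surrogate envelopes
(identical amplitude spectra, destroyed temporal alignment, 50
repetitions).

## Worked example

```python
import numpy as np
from musictrf.synthetic import StimulusSpec, synth_audio
from musictrf.tonal import sparse_tonal_encode, feature_descriptives

spec = StimulusSpec((("C major", 4.0), ("F# major", 4.0)), 120.0, "4/4",
                    stimulus_id="demo")
audio, beats, measures = synth_audio(spec, seed=0)
series = sparse_tonal_encode(audio, spec.fs_audio, beats.onsets_s)
print("key clarity :", np.round(series.key_clarity, 3))
print("stability   :", np.round(series.tonal_stability, 3))
```

prints

```
key clarity : [0.829 0.829 0.829 0.829 0.829 0.829 0.829 0.829 0.833 0.833 0.833 0.833
 0.833 0.833 0.833 0.833]
stability   : [1.    1.    1.    1.    1.    1.    1.    1.    0.182 0.206 0.236 0.274
 0.321 0.379 0.447 0.519]
```

Key clarity is context-free: the C-major and F♯-major block chords imply
their keys equally strongly throughout (≈0.83). Tonal stability is
context-dependent: it is 1 while the piece sits in C major, collapses to
0.18 at the abrupt modulation to the tritone-distant F♯ major (the most
distant key on the circle of fifths), then recovers as the new key
accumulates into the running tonal context. `feature_descriptives(series)`
summarizes the series per stimulus (here clarity 0.83 ± 0.00, stability
0.66 ± 0.36).

## Command-line pipeline

```sh
musictrf simulate --out sim --seed 7 --participants 9 --channels 64
musictrf extract-features --audio sim/s01.wav --beats sim/s01_beats.tsv \
    --out-prefix feat/s01 --fs 128
musictrf fit --data sim --out fits --lags 0:250 \
    --model env --model env+beat --model env+meter
musictrf control --data sim --n-rand 50 --out fits --lags 0:250
musictrf compare --accuracies fits --perms 10000 --seed 7 --out report.json
```

`simulate` writes a 12-stimulus dataset shaped like a familiar-melody
listening study (half 3/4, half 4/4, 6.9–13.9 s, five repetitions → 60
trials per participant) with planted TRF kernels: envelope everywhere,
beat on a central channel patch, an accent-contrast meter code on a
frontal band. `compare` should then report spatially distinct significant
beat (central) and meter (frontal) clusters, and null results for the
tonal features that were not planted.

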