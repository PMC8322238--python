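"""Broadband temporal envelope and phase-randomized surrogates.

The envelope is |Hilbert transform| of the audio, low-pass anti-alias
filtered and resampled to the EEG rate. Surrogates randomize the Fourier
phases while preserving the amplitude spectrum bin-for-bin (Hermitian
phase draw, DC and Nyquist untouched), destroying temporal alignment with
the stimulus but keeping identical spectral content.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class Envelope:
    samples: np.ndarray
    fs_hz: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def hilbert_envelope(
    audio: np.ndarray, fs_hz: float, target_fs_hz: float, source_id: str = ""
) -> Envelope:
    """|analytic signal|, anti-alias low-pass filtered, resampled to target.

    The anti-alias filter is a zero-phase FIR low-pass with cutoff at
    0.45 x target rate, applied before polyphase resampling.
    """
    x = np.asarray(audio, dtype=float)
    if x.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    if target_fs_hz > fs_hz:
        raise ValueError(f"target rate {target_fs_hz} exceeds audio rate {fs_hz}")
    env = np.abs(signal.hilbert(x))
    if target_fs_hz < fs_hz:
        cutoff = 0.45 * target_fs_hz
        numtaps = 2 * int(2 * fs_hz / cutoff) + 1
        fir = signal.firwin(numtaps, cutoff, fs=fs_hz)
        env = signal.filtfilt(fir, [1.0], env, padlen=min(len(env) - 1, 3 * numtaps))
        ratio = Fraction(int(round(target_fs_hz * 1000)), int(round(fs_hz * 1000)))
        env = signal.resample_poly(env, ratio.numerator, ratio.denominator)
    return Envelope(np.maximum(env, 0.0), target_fs_hz, source_id)


def phase_randomize(env: Envelope, rng: np.random.Generator) -> Envelope:
    """Surrogate with identical amplitude spectrum but random phases.

    DC (and Nyquist for even lengths) keep their original values so the
    output is exactly real; the surrogate may go negative, which is
    acceptable for a control regressor. Deterministic given the generator
    state.
    """
    x = env.samples
    n = len(x)
    spec = np.fft.rfft(x)
    phases = np.angle(spec)
    # randomize interior bins only; keep DC and (even-n) Nyquist fixed
    hi = len(spec) - 1 if n % 2 == 0 else len(spec)
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, hi - 1)
    surrogate = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)
    return Envelope(surrogate, env.fs_hz, env.source_id)


def surrogate_ensemble(
    env: Envelope, n_surrogates: int = 50, seed: int = 0
) -> list[Envelope]:
    """Seeded ensemble of phase-randomized surrogates.

    One surrogate per randomization repetition; within a repetition the
    same surrogate is reused for every repeated trial of the stimulus.
    """
    rng = np.random.default_rng(seed)
    return [phase_randomize(env, rng) for _ in range(n_surrogates)]
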