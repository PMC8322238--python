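"""EEG preprocessing: windowed-sinc FIR band-pass, resample, trim, Z-score.

The band of interest is 1–8 Hz (low-frequency activity carrying
music-related information). Filtering uses a Hamming windowed-sinc FIR
applied zero-phase; the signal is then polyphase-resampled to the
analysis rate, trimmed by 100 ms at music onset and offset to avoid
transients, and Z-scored per channel within the trial.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .trf import lag_indices, zscore


def bandpass_fir(
    fs_hz: float, low_hz: float, high_hz: float, transition_hz: float = 1.0
) -> np.ndarray:
    """Hamming windowed-sinc band-pass FIR taps (odd length)."""
    numtaps = int(np.ceil(3.3 * fs_hz / transition_hz)) | 1
    return signal.firwin(
        numtaps, [low_hz, high_hz], fs=fs_hz, pass_zero=False, window="hamming"
    )


def preprocess_eeg(
    raw: np.ndarray, fs_in: float, config: PipelineConfig | None = None
) -> np.ndarray:
    """Channels × time raw EEG → band-passed, resampled, trimmed, Z-scored.

    Raises if the trimmed epoch is shorter than the configured lag window.
    """
    cfg = config or PipelineConfig()
    low, high = cfg.bandpass_hz
    if fs_in < 2.0 * high:
        raise ValueError(f"input rate {fs_in} Hz below 2 x band edge {high} Hz")
    x = np.atleast_2d(np.asarray(raw, dtype=float))
    taps = bandpass_fir(fs_in, low, high)
    padlen = min(x.shape[1] - 1, 3 * len(taps))
    x = signal.filtfilt(taps, [1.0], x, axis=1, padlen=padlen)
    if cfg.fs_target != fs_in:
        ratio = Fraction(int(round(cfg.fs_target * 1000)), int(round(fs_in * 1000)))
        x = signal.resample_poly(x, ratio.numerator, ratio.denominator, axis=1)
    trim = int(round(cfg.epoch_trim_s * cfg.fs_target))
    x = x[:, trim : x.shape[1] - trim]
    lag_span = len(lag_indices(cfg.tmin_ms, cfg.tmax_ms, cfg.fs_target))
    if x.shape[1] <= lag_span:
        raise ValueError(
            f"epoch of {x.shape[1]} samples shorter than lag window ({lag_span})"
        )
    return zscore(x, axis=1)
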