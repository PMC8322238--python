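"""Beat and meter impulse regressors.

Beats are encoded as a unit impulse train (1 at each beat sample, 0
elsewhere). Meter is encoded as three separate impulse trains by accent
strength — strong / middle / weak — following the Western classical accent
scheme: in 4/4, beats 1/2/3/4 map to strong/weak/middle/weak; in 3/4,
beats 1/2/3 map to strong/weak/weak (the middle tier is kept as an
all-zero regressor for dimensional consistency across time signatures).
The tiers encode the strength of a beat, not its position in the bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

BEATS_PER_BAR = {"3/4": 3, "4/4": 4}

#: beat-in-bar (1-based) → accent tier, per time signature
ACCENT_SCHEME = {
    "4/4": {1: "strong", 2: "weak", 3: "middle", 4: "weak"},
    "3/4": {1: "strong", 2: "weak", 3: "weak"},
}

TIER_NAMES = ("strong", "middle", "weak")


@dataclass
class BeatGrid:
    """Beat annotations: onset times, 1-based position in bar, signature."""

    onsets_s: np.ndarray
    beat_in_bar: np.ndarray
    time_signature: str

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.beat_in_bar = np.asarray(self.beat_in_bar, dtype=int)
        if self.time_signature not in BEATS_PER_BAR:
            raise ValueError(f"unsupported time signature {self.time_signature!r}")
        if len(self.onsets_s) != len(self.beat_in_bar):
            raise ValueError("onsets and beat_in_bar must have equal length")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("beat onsets must be strictly increasing")
        bpb = BEATS_PER_BAR[self.time_signature]
        bad = np.flatnonzero((self.beat_in_bar < 1) | (self.beat_in_bar > bpb))
        if len(bad):
            raise ValueError(
                f"beat_in_bar out of range for {self.time_signature} "
                f"at beats {bad.tolist()} (values {self.beat_in_bar[bad].tolist()})"
            )

    def __len__(self) -> int:
        return len(self.onsets_s)

    def measure_onsets(self) -> np.ndarray:
        """Onset times of downbeats (beat 1 of each bar)."""
        return self.onsets_s[self.beat_in_bar == 1]


@dataclass
class ImpulseRegressor:
    """Sparse feature channel on the EEG time grid."""

    samples: np.ndarray
    fs_hz: float
    name: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def _to_sample(t: float, fs_hz: float) -> int:
    # round half away from zero; +-1 sample at 128 Hz is within TRF resolution
    return int(np.floor(t * fs_hz + 0.5))


def _impulses(times_s: np.ndarray, fs_hz: float, n_samples: int, name: str,
              values: np.ndarray | None = None) -> ImpulseRegressor:
    out = np.zeros(n_samples)
    beyond = [t for t in times_s if _to_sample(t, fs_hz) >= n_samples]
    if beyond:
        raise ValueError(f"events beyond trial end ({n_samples / fs_hz:.3f}s): {beyond}")
    n_collisions = 0
    for i, t in enumerate(times_s):
        s = _to_sample(t, fs_hz)
        if out[s] != 0.0:
            n_collisions += 1
        out[s] = 1.0 if values is None else values[i]
    if n_collisions:
        logger.warning("%d impulse collisions in %s (kept single impulse)",
                       n_collisions, name)
    return ImpulseRegressor(out, fs_hz, name)


def beat_impulses(grid: BeatGrid, fs_hz: float, n_samples: int) -> ImpulseRegressor:
    """Unit impulse train: 1 at each beat sample, 0 otherwise."""
    return _impulses(grid.onsets_s, fs_hz, n_samples, "beat")


def meter_tiers(
    grid: BeatGrid, fs_hz: float, n_samples: int
) -> dict[str, ImpulseRegressor]:
    """Three accent-tier impulse trains (strong / middle / weak).

    The tiers partition the beat set: their pointwise maximum equals the
    beat impulse train. In 3/4 the middle tier is all-zero by the accent
    scheme (retained so model dimensionality matches 4/4 stimuli; ridge
    regularization renders the inert column harmless).
    """
    scheme = ACCENT_SCHEME[grid.time_signature]
    out = {}
    for tier in TIER_NAMES:
        times = grid.onsets_s[[scheme[b] == tier for b in grid.beat_in_bar]]
        out[tier] = _impulses(times, fs_hz, n_samples, f"meter_{tier}")
    return out


def sparse_value_encode(
    event_times_s: np.ndarray,
    values: np.ndarray,
    fs_hz: float,
    n_samples: int,
    name: str,
) -> ImpulseRegressor:
    """Place a feature value at each event-onset sample, 0 elsewhere.

    NaN values (dropped events) produce no impulse.
    """
    event_times_s = np.asarray(event_times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(event_times_s) != len(values):
        raise ValueError("event times and values must have equal length")
    keep = ~np.isnan(values)
    return _impulses(event_times_s[keep], fs_hz, n_samples, name, values[keep])
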