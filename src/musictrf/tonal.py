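"""Hierarchical tonal features for continuous music.

Implements the Krumhansl–Schmuckler key-finding front end (chromagram →
key-strength correlation against the 24 major/minor tonal-hierarchy
profiles), *key clarity* (the maximal key strength, a context-free measure
of how strongly any key is implied), and *tonal stability* — the angular
similarity between the current frame's key-strength vector and the
cumulative moving average of all preceding frames' vectors:

    s(t) = 1 − arccos( v(t)·v̄(t−1) / (‖v(t)‖ ‖v̄(t−1)‖) ) / π

which is 1 for parallel vectors, 0.5 for orthogonal, 0 for antiparallel.
Tonal features are sparse-encoded on beat- or measure-spanning windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Krumhansl & Kessler probe-tone ratings: perceived stability of each pitch
#: class (relative to the tonic at index 0) in a major / minor key context.
#: These are the "tonal hierarchy" profiles used as ideal chromagrams.
KK_MAJOR = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
KK_MINOR = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)

PITCH_CLASSES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]

#: Reference tuning: A4 = 440 Hz; pitch class of A is index 9 (C = 0).
A4_HZ = 440.0
_A_PITCH_CLASS = 9


@dataclass(frozen=True)
class KeyProfile:
    """Tonal-hierarchy profile of one key (probe-tone stability ratings)."""

    pitch_class_weights: np.ndarray
    mode: str  # "major" | "minor"
    tonic: int  # pitch-class index 0..11, C = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.pitch_class_weights, dtype=float)
        if w.shape != (12,) or np.any(w <= 0):
            raise ValueError("profile needs 12 strictly positive weights")
        if self.mode not in ("major", "minor"):
            raise ValueError(f"mode must be major/minor, got {self.mode!r}")
        object.__setattr__(self, "pitch_class_weights", w)


def key_names() -> list[str]:
    """Names of the 24 keys, 12 major then 12 minor, tonics C..B."""
    return [f"{pc} major" for pc in PITCH_CLASSES] + [
        f"{pc} minor" for pc in PITCH_CLASSES
    ]


def key_profiles() -> list[KeyProfile]:
    """All 24 key profiles: the base profiles rotated to every tonic."""
    out = []
    for tonic in range(12):
        out.append(KeyProfile(np.roll(KK_MAJOR, tonic), "major", tonic))
    for tonic in range(12):
        out.append(KeyProfile(np.roll(KK_MINOR, tonic), "minor", tonic))
    return out


def profile_matrix() -> np.ndarray:
    """(24, 12) array of profile weights; row order matches :func:`key_names`."""
    return np.stack([p.pitch_class_weights for p in key_profiles()])


@dataclass(frozen=True)
class ChromaVector:
    """12 nonnegative pitch-class energies for one analysis window."""

    energies: np.ndarray
    window_start_s: float
    window_end_s: float
    is_silent: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (12,) or np.any(e < 0):
            raise ValueError("chroma needs 12 nonnegative energies")
        if not self.window_end_s > self.window_start_s:
            raise ValueError("window_end_s must exceed window_start_s")
        object.__setattr__(self, "energies", e)


def chromagram(
    audio_window: np.ndarray,
    fs_hz: float,
    *,
    pitch_floor_hz: float = 30.0,
    pitch_ceiling_hz: float = 3000.0,
    window_start_s: float = 0.0,
) -> ChromaVector:
    """Fold the magnitude spectrum of one window onto 12 pitch classes.

    FFT bin energies (squared magnitudes) between ``pitch_floor_hz`` and
    ``pitch_ceiling_hz`` are assigned to the nearest equal-temperament pitch
    class (A4 = 440 Hz reference). The window must span at least two periods
    of the pitch floor so the lowest pitches are resolvable; the sample rate
    must exceed twice the analysis ceiling.
    """
    x = np.asarray(audio_window, dtype=float)
    if x.ndim != 1:
        raise ValueError("audio window must be mono (1-D)")
    min_len = int(np.ceil(2.0 * fs_hz / pitch_floor_hz))
    if len(x) < min_len:
        raise ValueError(
            f"window too short: {len(x)} samples < minimum {min_len} "
            f"(2 periods of {pitch_floor_hz} Hz at {fs_hz} Hz)"
        )
    if fs_hz <= 2.0 * pitch_ceiling_hz:
        raise ValueError(
            f"sample rate {fs_hz} Hz must exceed 2 x ceiling {pitch_ceiling_hz} Hz"
        )
    end_s = window_start_s + len(x) / fs_hz
    if not np.any(x):
        return ChromaVector(np.zeros(12), window_start_s, end_s, is_silent=True)

    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs_hz)
    band = (freqs >= pitch_floor_hz) & (freqs <= pitch_ceiling_hz)
    pc = (
        np.round(12.0 * np.log2(freqs[band] / A4_HZ)).astype(int) + _A_PITCH_CLASS
    ) % 12
    energies = np.bincount(pc, weights=spec[band], minlength=12)
    return ChromaVector(energies, window_start_s, end_s)


def key_strength(chroma: ChromaVector | np.ndarray) -> np.ndarray:
    """24 Pearson correlations of a chroma against the 24 key profiles.

    Order: 12 major then 12 minor (tonics C..B). A zero-variance chroma
    (silence or perfectly flat energies) makes the correlation undefined:
    the result is all-NaN and the caller is expected to drop the event.
    """
    c = chroma.energies if isinstance(chroma, ChromaVector) else np.asarray(chroma, float)
    if c.shape != (12,):
        raise ValueError("chroma must have 12 entries")
    cc = c - c.mean()
    denom_c = np.sqrt(np.sum(cc**2))
    if denom_c == 0.0:
        logger.warning("zero-variance chroma: key strength undefined")
        return np.full(24, np.nan)
    P = profile_matrix()
    Pc = P - P.mean(axis=1, keepdims=True)
    denom_p = np.sqrt(np.sum(Pc**2, axis=1))
    return (Pc @ cc) / (denom_p * denom_c)


@dataclass(frozen=True)
class KeyClarity:
    clarity: float
    key_index: int
    key_name: str


def key_clarity(ks: np.ndarray) -> KeyClarity:
    """Maximal key strength and its key (ties: lowest key index, logged)."""
    ks = np.asarray(ks, dtype=float)
    if ks.shape != (24,):
        raise ValueError("key-strength vector must have 24 entries")
    if np.any(np.isnan(ks)):
        raise ValueError("key-strength vector contains NaN")
    idx = int(np.argmax(ks))  # argmax returns the first (lowest) index on ties
    if np.sum(ks == ks[idx]) > 1:
        logger.info("key clarity tie; reporting lowest key index %d", idx)
    return KeyClarity(float(ks[idx]), idx, key_names()[idx])


def angular_similarity(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Angular similarity 1 − θ/π and the angle θ between two vectors.

    θ is evaluated as 2·atan2(‖û−v̂‖, ‖û+v̂‖) on the unit-normalized
    vectors, which is algebraically arccos of the clamped normalized dot
    product but numerically exact for (anti)parallel pairs where the naive
    arccos loses half its precision. Raises on zero-norm input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angular similarity undefined for zero-norm vectors")
    uh, vh = u / nu, v / nv
    theta = 2.0 * float(np.arctan2(np.linalg.norm(uh - vh), np.linalg.norm(uh + vh)))
    return 1.0 - theta / np.pi, theta


@dataclass(frozen=True)
class TonalStabilityValue:
    value: float
    angle_rad: float


@dataclass(frozen=True)
class CumulativeKeyStrength:
    """Running arithmetic mean of key-strength vectors v̄(j) = Σᵢ v(i)/j."""

    mean_vector: np.ndarray = field(default_factory=lambda: np.zeros(24))
    n_frames: int = 0

    def update(self, v_new: np.ndarray) -> "CumulativeKeyStrength":
        v_new = np.asarray(v_new, dtype=float)
        n = self.n_frames
        mean = (np.asarray(self.mean_vector, float) * n + v_new) / (n + 1)
        return CumulativeKeyStrength(mean, n + 1)


def tonal_stability(
    v_t: np.ndarray, v_bar_prev: CumulativeKeyStrength
) -> TonalStabilityValue:
    """Tonal stability of frame t against the running key-strength context."""
    if v_bar_prev.n_frames < 1:
        raise ValueError("cumulative context must contain at least one frame")
    value, theta = angular_similarity(v_t, v_bar_prev.mean_vector)
    return TonalStabilityValue(value, theta)


@dataclass
class TonalEventSeries:
    """Per-event tonal features sparse-encoded at beats or measures.

    Events whose window had undefined key strength (silence / flat chroma)
    are dropped; ``n_dropped`` counts them.
    """

    event_times_s: np.ndarray
    key_clarity: np.ndarray
    tonal_stability: np.ndarray
    key_index: np.ndarray
    granularity: str  # "beat" | "measure"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")
        if not (len(t) == len(self.key_clarity) == len(self.tonal_stability)):
            raise ValueError("feature arrays must match event times in length")
        self.event_times_s = t

    def __len__(self) -> int:
        return len(self.event_times_s)


def sparse_tonal_encode(
    audio: np.ndarray,
    fs_hz: float,
    event_times_s: np.ndarray,
    *,
    granularity: str = "beat",
    pitch_floor_hz: float = 30.0,
    pitch_ceiling_hz: float = 3000.0,
    window_s: float | None = None,
) -> TonalEventSeries:
    """Compute key clarity and tonal stability on event-spanning windows.

    For event i the analysis window is [eᵢ, eᵢ₊₁); the last window extends
    to the end of the audio. ``window_s`` switches to fixed-length windows
    anchored at each event instead. The first (valid) event initializes the
    cumulative context with its own key-strength vector, so its stability is
    1 by convention; afterwards the context is updated with every frame and
    stability of frame t is measured against the context up to t−1.
    """
    audio = np.asarray(audio, dtype=float)
    times = np.asarray(event_times_s, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 events for sparse tonal encoding")
    duration = len(audio) / fs_hz
    beyond = times[times >= duration]
    if len(beyond):
        raise ValueError(f"events beyond audio duration {duration:.3f}s: {beyond}")

    kept_t, kept_clar, kept_stab, kept_key = [], [], [], []
    n_dropped = 0
    context: CumulativeKeyStrength | None = None
    for i, t0 in enumerate(times):
        if window_s is not None:
            t1 = min(t0 + window_s, duration)
        else:
            t1 = times[i + 1] if i + 1 < len(times) else duration
        i0, i1 = int(round(t0 * fs_hz)), int(round(t1 * fs_hz))
        if i1 - i0 < int(np.ceil(2.0 * fs_hz / pitch_floor_hz)):
            # terminal slivers shorter than two pitch-floor periods cannot
            # support a chromagram: drop the event rather than fabricate one
            n_dropped += 1
            logger.info("dropping event %d at %.3fs (window too short)", i, t0)
            continue
        chroma = chromagram(
            audio[i0:i1],
            fs_hz,
            pitch_floor_hz=pitch_floor_hz,
            pitch_ceiling_hz=pitch_ceiling_hz,
            window_start_s=t0,
        )
        v = key_strength(chroma)
        if np.any(np.isnan(v)):
            n_dropped += 1
            logger.info("dropping event %d at %.3fs (undefined key strength)", i, t0)
            continue
        clar = key_clarity(v)
        if context is None:
            context = CumulativeKeyStrength(v, 1)  # v̄(0) := v(1) → s(1) = 1
            stab = TonalStabilityValue(1.0, 0.0)
        else:
            stab = tonal_stability(v, context)
            context = context.update(v)
        kept_t.append(t0)
        kept_clar.append(clar.clarity)
        kept_stab.append(stab.value)
        kept_key.append(clar.key_index)

    return TonalEventSeries(
        np.array(kept_t),
        np.array(kept_clar),
        np.array(kept_stab),
        np.array(kept_key, dtype=int),
        granularity,
        n_dropped,
    )


@dataclass(frozen=True)
class KeySpacePCA:
    coordinates_2d: np.ndarray  # (n_keys, 2) projection on the first two PCs
    variance_fractions: np.ndarray
    percent_first_two: float
    key_names: list[str]


def keyspace_pca(subset: str = "all24") -> KeySpacePCA:
    """Centered PCA of the ideal-profile key-strength vectors.

    Each of the 24 key profiles, used as an ideal chromagram, is correlated
    against all 24 profiles, giving 24 key-strength vectors in R^24; these
    are stacked, centered, and decomposed. ``subset='major12'`` restricts
    the rows to the 12 major keys (both variants are reported because the
    literature is ambiguous about which set the quoted figure used).
    """
    from sklearn.decomposition import PCA

    names = key_names()
    V = np.stack([key_strength(p) for p in profile_matrix()])
    if subset == "major12":
        V, names = V[:12], names[:12]
    elif subset != "all24":
        raise ValueError("subset must be 'all24' or 'major12'")
    pca = PCA()
    coords = pca.fit_transform(V)[:, :2]
    frac = pca.explained_variance_ratio_
    return KeySpacePCA(coords, frac, float(frac[:2].sum() * 100.0), names)


def feature_descriptives(series: TonalEventSeries, stimulus_id: str = "") -> dict:
    """Per-stimulus descriptives: mean ± SD of clarity/stability and their r.

    Correlation is Pearson with its p-value; a constant feature makes the
    correlation undefined and both r and p are reported as NaN.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 events for descriptive statistics")
    clar, stab = series.key_clarity, series.tonal_stability
    if np.std(clar) == 0.0 or np.std(stab) == 0.0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(clar, stab)
    return {
        "stimulus_id": stimulus_id,
        "n_events": len(series),
        "granularity": series.granularity,
        "clarity_mean": float(np.mean(clar)),
        "clarity_sd": float(np.std(clar, ddof=1)),
        "stability_mean": float(np.mean(stab)),
        "stability_sd": float(np.std(stab, ddof=1)),
        "clarity_stability_r": float(r),
        "clarity_stability_p": float(p),
    }
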