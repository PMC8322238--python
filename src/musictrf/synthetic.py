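"""Synthetic stimuli, annotations, and EEG with known ground truth.

Audio is synthesized as sine-wave block triads of a scheduled key plan,
articulated on a metronomic beat grid — chroma content is therefore
analytically known, which makes the tonal features verifiable against the
closed-form statistic. EEG is generated from the same forward model the
analysis assumes: feature regressors convolved with planted TRF kernels
on declared spatial supports, plus Gaussian (optionally AR(1)) noise
scaled to a target SNR, then Z-scored per trial like real preprocessing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .envelope import hilbert_envelope
from .rhythm import BEATS_PER_BAR, BeatGrid, beat_impulses, meter_tiers, sparse_value_encode
from .tonal import PITCH_CLASSES, sparse_tonal_encode
from .trf import Trial, zscore

C4_HZ = 261.6255653005986  # middle C, equal temperament, A4 = 440 Hz

_TRIAD_INTERVALS = {"major": (0, 4, 7), "minor": (0, 3, 7)}


def _triad_freqs(key: str) -> list[float]:
    tonic_name, mode = key.split()
    tonic = PITCH_CLASSES.index(tonic_name)
    return [C4_HZ * 2.0 ** ((tonic + iv) / 12.0) for iv in _TRIAD_INTERVALS[mode]]


@dataclass(frozen=True)
class StimulusSpec:
    """Plan for one synthetic stimulus: keys, tempo, signature, rate."""

    key_plan: tuple[tuple[str, float], ...]  # (key name, duration seconds)
    tempo_bpm: float
    time_signature: str
    fs_audio: float = 8000.0
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        if not 60.0 <= self.tempo_bpm <= 240.0:
            raise ValueError(f"tempo {self.tempo_bpm} outside [60, 240] BPM")
        if any(d <= 0 for _, d in self.key_plan):
            raise ValueError("key-plan durations must be positive")
        if self.time_signature not in BEATS_PER_BAR:
            raise ValueError(f"unsupported signature {self.time_signature!r}")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.key_plan))


def synth_audio(
    spec: StimulusSpec, seed: int = 0
) -> tuple[np.ndarray, BeatGrid, np.ndarray]:
    """Render block-triad audio and its beat grid.

    Each beat articulates the triad of the currently scheduled key with an
    exponentially decaying amplitude. Returns (audio, beat grid, measure
    onset times). Deterministic under the seed (per-note amplitude jitter).
    """
    rng = np.random.default_rng(seed)
    fs = spec.fs_audio
    period = 60.0 / spec.tempo_bpm
    duration = spec.duration_s
    n_beats = int(np.ceil(duration / period - 1e-9))  # beats at k·period < duration
    bpb = BEATS_PER_BAR[spec.time_signature]
    onsets = np.arange(n_beats) * period
    beat_in_bar = np.arange(n_beats) % bpb + 1
    grid = BeatGrid(onsets, beat_in_bar, spec.time_signature)

    key_edges = np.cumsum([0.0] + [d for _, d in spec.key_plan])
    keys = [k for k, _ in spec.key_plan]
    audio = np.zeros(int(round(duration * fs)))
    for t0 in onsets:
        key = keys[min(np.searchsorted(key_edges, t0, side="right") - 1, len(keys) - 1)]
        i0 = int(round(t0 * fs))
        n = min(int(round(period * fs)), len(audio) - i0)
        t = np.arange(n) / fs
        decay = np.exp(-t / (period / 2.0))
        amp = 0.3 * (1.0 + 0.05 * rng.standard_normal())
        note = sum(np.sin(2 * np.pi * f * t) for f in _triad_freqs(key))
        audio[i0 : i0 + n] += amp * decay * note
    return audio, grid, grid.measure_onsets()


@dataclass
class GroundTruth:
    """Planted kernels and noise model of the synthetic forward problem."""

    kernels: dict[str, np.ndarray]  # feature → (D,) temporal kernel
    spatial_support: dict[str, np.ndarray]  # feature → channel indices
    channel_gains: dict[str, np.ndarray]  # feature → gain per support channel
    lag_samples: np.ndarray
    snr_db: float
    seed: int
    ar1_phi: float = 0.0

    def kernel_matrix(self, feature: str, n_channels: int) -> np.ndarray:
        """(D, C) kernel with zeros off the declared spatial support."""
        K = np.zeros((len(self.lag_samples), n_channels))
        K[:, self.spatial_support[feature]] = (
            self.kernels[feature][:, None] * self.channel_gains[feature][None, :]
        )
        return K


def _smooth_kernel(lags: np.ndarray, fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Random smooth biphasic kernel supported on the lag span."""
    lag_s = lags / fs_hz
    center = rng.uniform(0.05, 0.25)
    width = rng.uniform(0.03, 0.08)
    k = np.sin(2 * np.pi * (lag_s - center) / (4 * width)) * np.exp(
        -((lag_s - center) ** 2) / (2 * width**2)
    )
    norm = np.linalg.norm(k)
    return k / norm if norm > 0 else k


def make_ground_truth(
    features: list[str],
    n_channels: int,
    lag_samples: np.ndarray,
    fs_hz: float,
    snr_db: float,
    seed: int,
    spatial_support: dict[str, np.ndarray] | None = None,
    ar1_phi: float = 0.0,
) -> GroundTruth:
    """Draw smooth random kernels per feature with declared supports."""
    rng = np.random.default_rng(seed)
    supports = spatial_support or {
        f: np.arange(n_channels) for f in features
    }
    kernels, gains = {}, {}
    for f in features:
        kernels[f] = _smooth_kernel(lag_samples, fs_hz, rng)
        gains[f] = rng.uniform(0.5, 1.0, size=len(supports[f]))
    return GroundTruth(kernels, supports, gains, np.asarray(lag_samples), snr_db,
                       seed, ar1_phi)


def default_patches(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Central (3×3) and frontal (top two rows) patches on a square grid.

    The beat kernels live on the central patch and the meter kernels on
    the frontal band, mimicking the spatial dissociation the framework is
    designed to detect.
    """
    side = int(np.sqrt(n_channels))
    if side * side != n_channels:
        raise ValueError("default patches require a square channel grid")
    mid = side // 2
    rows = [r for r in (mid - 1, mid, mid + 1) if 0 <= r < side]
    central = np.array([r * side + c for r in rows for c in rows])
    frontal = np.arange(min(2 * side, n_channels))
    return central, frontal


def dissociation_ground_truth(
    n_channels: int,
    lag_samples: np.ndarray,
    fs_hz: float,
    snr_db: float,
    seed: int,
) -> GroundTruth:
    """Ground truth embodying the central-beat / frontal-meter dissociation.

    Envelope kernels cover all channels; a uniform beat kernel lives on the
    central patch; the frontal band carries a pure accent *contrast* — tier
    kernels that sum to zero across strong/middle/weak — so a uniform beat
    regressor explains none of the frontal signal and the meter family's
    unique contribution is spatially separable from beat's.
    """
    rng = np.random.default_rng(seed)
    central, frontal = default_patches(n_channels)
    lags = np.asarray(lag_samples)
    k_env = _smooth_kernel(lags, fs_hz, rng)
    k_beat = _smooth_kernel(lags, fs_hz, rng)
    k_strong = _smooth_kernel(lags, fs_hz, rng)
    k_middle = _smooth_kernel(lags, fs_hz, rng)
    k_weak = -(k_strong + k_middle)  # zero mean across tiers: accent only
    support = {
        "envelope": np.arange(n_channels),
        "beat": central,
        "strong": frontal,
        "middle": frontal,
        "weak": frontal,
    }
    kernels = {"envelope": k_env, "beat": k_beat, "strong": k_strong,
               "middle": k_middle, "weak": k_weak}
    gains = {f: rng.uniform(0.5, 1.0, size=len(s)) for f, s in support.items()}
    # tiers share one gain pattern so the zero-sum contrast holds per channel
    gains["middle"] = gains["strong"]
    gains["weak"] = gains["strong"]
    return GroundTruth(kernels, support, gains, lags, snr_db, seed)


def _convolve_lagged(x: np.ndarray, kernel: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """y[t] = Σ_d kernel[d] · x[t−d] with d over the (possibly negative) lags."""
    T = len(x)
    z = np.convolve(x, kernel)
    d_min = int(lags[0])
    y = np.zeros(T)
    idx = np.arange(T) - d_min
    ok = (idx >= 0) & (idx < len(z))
    y[ok] = z[idx[ok]]
    return y


def synth_eeg(
    regressors: dict[str, np.ndarray] | list[dict[str, np.ndarray]],
    truth: GroundTruth,
    n_channels: int,
    n_trials: int,
    fs_hz: float,
    seed: int = 0,
    stimulus_ids: list[str] | None = None,
) -> list[Trial]:
    """Generate trials y = Σ_f (x_f ⊛ k_f) + ε at the declared SNR.

    ``regressors`` is one dict (same stimulus every trial) or a list
    cycled over trials. Noise is white Gaussian (AR(1) with coefficient
    ``truth.ar1_phi`` if nonzero), scaled per channel so signal-carrying
    channels hit ``snr_db``; channels with no planted signal receive noise
    at the mean noise scale of the signal channels (flagged: noise-only).
    Each trial is Z-scored per channel, mirroring the preprocessing.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    reg_list = regressors if isinstance(regressors, list) else [regressors]
    trials = []
    for i in range(n_trials):
        regs = reg_list[i % len(reg_list)]
        T = len(next(iter(regs.values())))
        sig = np.zeros((n_channels, T))
        for f, k in truth.kernels.items():
            if f not in regs:
                raise KeyError(f"ground truth feature {f!r} missing from regressors")
            K = truth.kernel_matrix(f, n_channels)
            drive = zscore(regs[f])
            for c in truth.spatial_support[f]:
                sig[c] += _convolve_lagged(drive, K[:, c], truth.lag_samples)
        noise = rng.standard_normal((n_channels, T))
        if truth.ar1_phi:
            noise = lfilter([1.0], [1.0, -truth.ar1_phi], noise, axis=1)
        noise /= noise.std(axis=1, keepdims=True)
        sig_var = sig.var(axis=1)
        has_signal = sig_var > 0
        snr_lin = 10.0 ** (truth.snr_db / 10.0)
        noise_sd = np.empty(n_channels)
        if has_signal.any():
            noise_sd[has_signal] = np.sqrt(sig_var[has_signal] / snr_lin)
            noise_sd[~has_signal] = noise_sd[has_signal].mean()
        else:
            noise_sd[:] = 1.0  # noise-only fallback; no signal anywhere
        eeg = zscore(sig + noise * noise_sd[:, None], axis=1)
        sid = stimulus_ids[i % len(stimulus_ids)] if stimulus_ids else f"trial{i}"
        trials.append(Trial(eeg, dict(regs), fs_hz, stimulus_id=sid))
    return trials


# --- study-shaped fixture bundle -------------------------------------------

#: 12 stimuli mirroring a familiar-melody listening study: half 3/4, half
#: 4/4, tempi 104–213 BPM, durations 6.9–13.9 s.
DEFAULT_STIMULI: list[tuple[str, float, str, float]] = [
    # (stimulus id, tempo, signature, duration)
    ("s01", 213.0, "3/4", 13.3),
    ("s02", 189.0, "3/4", 7.7),
    ("s03", 200.0, "4/4", 9.7),
    ("s04", 160.0, "4/4", 11.6),
    ("s11", 206.0, "3/4", 13.9),
    ("s12", 185.0, "3/4", 7.9),
    ("s13", 200.0, "4/4", 9.0),
    ("s14", 160.0, "4/4", 12.2),
    ("s21", 175.0, "3/4", 8.3),
    ("s22", 166.0, "3/4", 12.9),
    ("s23", 104.0, "4/4", 9.2),
    ("s24", 140.0, "4/4", 6.9),
]

_KEY_CYCLE = ["C major", "G major", "F major", "A minor", "D major", "E minor",
              "A# major", "D minor", "A major", "G minor", "D# major", "B minor"]


def default_stimulus_specs(fs_audio: float = 8000.0) -> list[StimulusSpec]:
    """The 12 fixture stimuli; each modulates to a related key halfway."""
    specs = []
    for i, (sid, bpm, sig, dur) in enumerate(DEFAULT_STIMULI):
        k1 = _KEY_CYCLE[i % len(_KEY_CYCLE)]
        k2 = _KEY_CYCLE[(i + 1) % len(_KEY_CYCLE)]
        plan = ((k1, dur / 2.0), (k2, dur / 2.0))
        specs.append(StimulusSpec(plan, bpm, sig, fs_audio, sid))
    return specs


def build_stimulus_regressors(
    spec: StimulusSpec,
    fs_eeg: float,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], BeatGrid, np.ndarray]:
    """Audio → full regressor set (envelope, beat, meter tiers, tonal)."""
    audio, grid, measures = synth_audio(spec, seed)
    n = int(round(spec.duration_s * fs_eeg))
    env = hilbert_envelope(audio, spec.fs_audio, fs_eeg, spec.stimulus_id)
    env_samples = env.samples[:n]
    if len(env_samples) < n:
        env_samples = np.pad(env_samples, (0, n - len(env_samples)))
    regs = {"envelope": env_samples, "beat": beat_impulses(grid, fs_eeg, n).samples}
    for tier, reg in meter_tiers(grid, fs_eeg, n).items():
        regs[tier] = reg.samples
    tonal = sparse_tonal_encode(audio, spec.fs_audio, grid.onsets_s)
    regs["clarity"] = sparse_value_encode(
        tonal.event_times_s, tonal.key_clarity, fs_eeg, n, "clarity"
    ).samples
    regs["stability"] = sparse_value_encode(
        tonal.event_times_s, tonal.tonal_stability, fs_eeg, n, "stability"
    ).samples
    return regs, grid, measures


def fixture_suite(
    out_dir: str | Path,
    seed: int = 0,
    n_participants: int = 9,
    n_repetitions: int = 5,
    n_channels: int = 64,
    fs_eeg: float = 128.0,
    fs_audio: float = 8000.0,
    snr_db: float = 0.0,
    write_wav: bool = True,
) -> dict:
    """Write a miniature dataset shaped like the study.

    12 stimuli (6 in 3/4, 6 in 4/4, 6.9–13.9 s), ``n_repetitions``
    repetitions each per participant (default 5 → 60 trials), simulated
    participants sharing planted kernels but with independent noise.
    Writes WAVs, beat-annotation TSVs, per-participant EEG arrays (.npz),
    ground-truth JSON, and a manifest; byte-identical under a fixed seed.
    Returns the manifest dict.
    """
    from .io import (
        write_beat_annotations,
        write_regressor_set,
        write_wav as _write_wav,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = default_stimulus_specs(fs_audio)
    lags = np.arange(0, int(np.ceil(0.35 * fs_eeg)) + 1)
    central, frontal = default_patches(n_channels)
    support = {
        "envelope": np.arange(n_channels),
        "beat": central,
        "strong": frontal, "middle": frontal, "weak": frontal,
        "clarity": np.array([], dtype=int),
        "stability": np.array([], dtype=int),
    }
    truth = make_ground_truth(
        list(support), n_channels, lags, fs_eeg, snr_db, seed, support
    )

    stim_regs = {}
    for i, spec in enumerate(specs):
        regs, grid, _ = build_stimulus_regressors(spec, fs_eeg, seed=seed + i)
        stim_regs[spec.stimulus_id] = regs
        write_regressor_set(out / f"regressors_{spec.stimulus_id}.tsv", regs, fs_eeg)
        if write_wav:
            audio, grid2, _ = synth_audio(spec, seed + i)
            _write_wav(out / f"{spec.stimulus_id}.wav", audio, spec.fs_audio)
            write_beat_annotations(out / f"{spec.stimulus_id}_beats.tsv", grid2)

    order = [s.stimulus_id for s in specs] * n_repetitions
    for p in range(n_participants):
        trials = synth_eeg(
            [stim_regs[sid] for sid in order],
            truth,
            n_channels,
            len(order),
            fs_eeg,
            seed=seed * 1000 + p + 1,
            stimulus_ids=order,
        )
        # .npy is byte-deterministic (no zip timestamps): concatenate trials
        # along time and store the boundaries alongside.
        bounds = np.concatenate([[0], np.cumsum([t.eeg.shape[1] for t in trials])])
        np.save(out / f"participant_{p:02d}_eeg.npy",
                np.concatenate([t.eeg for t in trials], axis=1))
        np.save(out / f"participant_{p:02d}_bounds.npy", bounds)
    (out / "stimulus_order.txt").write_text("\n".join(order) + "\n")

    truth_json = {
        "seed": seed,
        "snr_db": snr_db,
        "fs_eeg": fs_eeg,
        "lag_samples": truth.lag_samples.tolist(),
        "kernels": {f: k.tolist() for f, k in truth.kernels.items()},
        "spatial_support": {f: s.tolist() for f, s in truth.spatial_support.items()},
        "channel_gains": {f: g.tolist() for f, g in truth.channel_gains.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    manifest = {
        "seed": seed,
        "n_participants": n_participants,
        "n_repetitions": n_repetitions,
        "n_stimuli": len(specs),
        "trials_per_participant": len(order),
        "n_channels": n_channels,
        "fs_eeg": fs_eeg,
        "fs_audio": fs_audio,
        "snr_db": snr_db,
        "stimuli": [
            {"id": s.stimulus_id, "tempo_bpm": s.tempo_bpm,
             "time_signature": s.time_signature, "duration_s": s.duration_s}
            for s in specs
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def bundle_digest(out_dir: str | Path) -> str:
    """SHA-256 over the bundle's files (sorted by name) for reproducibility."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
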