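"""High-level orchestration: bundle loading, family fits, surrogate control.

Glues the stages together for the command-line interface and the
end-to-end validation runs: load a simulated (or equivalently formatted
real) dataset, fit every nested model family per participant with nested
leave-one-out cross-validation, average surrogate-envelope accuracies
over phase-randomization repetitions, and hand the participant × channel
accuracy maps to the cluster-permutation comparison suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .compare import MODEL_FAMILIES, grid_layout
from .config import PipelineConfig
from .envelope import Envelope, phase_randomize
from .io import read_regressor_set
from .trf import CVResult, Trial, loo_crossval


def load_bundle(path: str | Path) -> dict:
    """Load a fixture-suite bundle: per-participant trials + metadata."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    order = (path / "stimulus_order.txt").read_text().split()
    regs = {}
    for stim in manifest["stimuli"]:
        sid = stim["id"]
        regs[sid], fs = read_regressor_set(path / f"regressors_{sid}.tsv")
    participants = []
    for p in range(manifest["n_participants"]):
        eeg = np.load(path / f"participant_{p:02d}_eeg.npy")
        bounds = np.load(path / f"participant_{p:02d}_bounds.npy")
        trials = [
            Trial(eeg[:, bounds[i] : bounds[i + 1]], dict(regs[sid]),
                  manifest["fs_eeg"], stimulus_id=sid)
            for i, sid in enumerate(order)
        ]
        participants.append(trials)
    truth_path = path / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return {"participants": participants, "manifest": manifest,
            "regressors": regs, "order": order, "ground_truth": truth}


def fit_family(
    trials: list[Trial], family: str, cfg: PipelineConfig
) -> CVResult:
    """Nested-LOO cross-validated fit of one model family for one participant."""
    if family not in MODEL_FAMILIES:
        raise KeyError(f"unknown model family {family!r}; "
                       f"choose from {sorted(MODEL_FAMILIES)}")
    return loo_crossval(
        trials, MODEL_FAMILIES[family], cfg.lambda_grid, cfg.tmin_ms, cfg.tmax_ms
    )


def family_accuracies(
    participants: list[list[Trial]], family: str, cfg: PipelineConfig
) -> np.ndarray:
    """Participants × channels mean CV accuracy for one family."""
    return np.stack([fit_family(tr, family, cfg).mean_r for tr in participants])


def surrogate_envelope_accuracies(
    participants: list[list[Trial]],
    cfg: PipelineConfig,
    n_randomizations: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Envelope-family accuracies under phase-randomized envelopes.

    For each randomization repetition one surrogate is drawn per stimulus
    and reused for every repeated trial of that stimulus (and across
    participants); the envelope-only family is refit and scored, and the
    accuracies are averaged across repetitions.
    """
    n_rand = n_randomizations or cfg.n_phase_randomizations
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = participants[0][0].fs_hz
    stim_envs: dict[str, np.ndarray] = {}
    for trials in participants:
        for tr in trials:
            stim_envs.setdefault(tr.stimulus_id, tr.regressors["envelope"])
    acc = np.zeros((len(participants), participants[0][0].n_channels))
    for _ in range(n_rand):
        surrogates = {
            sid: phase_randomize(Envelope(env, fs, sid), rng).samples
            for sid, env in stim_envs.items()
        }
        for pi, trials in enumerate(participants):
            mod = [
                Trial(tr.eeg, {**tr.regressors, "envelope": surrogates[tr.stimulus_id]},
                      tr.fs_hz, tr.stimulus_id)
                for tr in trials
            ]
            acc[pi] += fit_family(mod, "env", cfg).mean_r
    return acc / n_rand


def square_grid_for(n_channels: int):
    """Square-grid channel layout for simulated data."""
    side = int(np.sqrt(n_channels))
    if side * side != n_channels:
        raise ValueError(f"{n_channels} channels do not form a square grid")
    return grid_layout(side, side)
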