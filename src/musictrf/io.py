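"""Readers and writers for the pipeline's on-disk formats.

Audio is WAV (PCM or float, downmixed to mono on read). Beat annotations
are tab-separated text with columns onset_s, bar, beat_in_bar,
time_signature. Regressor sets are TSV tables with a JSON sidecar naming
the sampling rate. Every pipeline run can emit a manifest (config, seeds,
input digests) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .rhythm import BeatGrid


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as mono float in [−1, 1]; returns (samples, fs)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(fs)


def write_wav(path: str | Path, audio: np.ndarray, fs_hz: float) -> None:
    """Write mono float audio as 16-bit PCM, peak-normalized if needed."""
    x = np.asarray(audio, dtype=float)
    peak = np.max(np.abs(x)) if len(x) else 0.0
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, int(round(fs_hz)), (x * 32767.0).astype(np.int16))


def read_beat_annotations(path: str | Path) -> BeatGrid:
    """Delimited text with columns onset_s, bar, beat_in_bar, time_signature."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "beat_in_bar", "time_signature"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    signatures = df["time_signature"].unique()
    if len(signatures) != 1:
        raise ValueError(f"mixed time signatures in {path}: {signatures}")
    return BeatGrid(
        df["onset_s"].to_numpy(float),
        df["beat_in_bar"].to_numpy(int),
        str(signatures[0]),
    )


def write_beat_annotations(path: str | Path, grid: BeatGrid) -> None:
    bpb = {"3/4": 3, "4/4": 4}[grid.time_signature]
    bar = np.arange(len(grid)) // bpb + 1
    pd.DataFrame(
        {
            "onset_s": grid.onsets_s,
            "bar": bar,
            "beat_in_bar": grid.beat_in_bar,
            "time_signature": grid.time_signature,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_regressor_set(
    path: str | Path, regressors: dict[str, np.ndarray], fs_hz: float
) -> None:
    """TSV of named feature channels + JSON sidecar with the sampling rate."""
    path = Path(path)
    pd.DataFrame(regressors).to_csv(path, sep="\t", index=False, float_format="%.8g")
    sidecar = {"fs_hz": fs_hz, "channels": list(regressors)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_regressor_set(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t")
    return {c: df[c].to_numpy(float) for c in meta["channels"]}, float(meta["fs_hz"])


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: dict, inputs: list[str | Path]) -> dict:
    """Record config, seeds, and input digests for bit-reproducibility."""
    manifest = {
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).is_file()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
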