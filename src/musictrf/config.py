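"""Pipeline configuration with the study-standard defaults.

Defaults: EEG analysis rate 128 Hz, 1–8 Hz band-pass, TRF lags −150 to
450 ms (79 delays at 128 Hz), a 21-point log-linear ridge grid from 2⁻¹⁰
to 2¹⁰, 10,000 permutations and bootstrap resamples, and 50 phase
randomizations for the surrogate control. All overridable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class PipelineConfig:
    fs_target: float = 128.0
    bandpass_hz: tuple[float, float] = (1.0, 8.0)
    tmin_ms: float = -150.0
    tmax_ms: float = 450.0
    n_lambda: int = 21
    lambda_min_exp: float = -10.0
    lambda_max_exp: float = 10.0
    n_permutations: int = 10_000
    n_bootstrap: int = 10_000
    n_phase_randomizations: int = 50
    alpha_forming: float = 0.05
    alpha_fwer: float = 0.05
    epoch_trim_s: float = 0.1  # drop 100 ms at music onset and offset
    seed: int = 0

    @property
    def lambda_grid(self) -> np.ndarray:
        return 2.0 ** np.linspace(self.lambda_min_exp, self.lambda_max_exp, self.n_lambda)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "bandpass_hz" in d:
            d["bandpass_hz"] = tuple(d["bandpass_hz"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
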