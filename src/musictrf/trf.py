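"""Ridge-regularized temporal response functions (TRFs).

The encoding model is a lagged FIR regression per EEG channel,

    y = X b + e,    b̂(λ) = (XᵀX + λI)⁻¹ Xᵀ y,

where X stacks P stimulus features over D time lags (Toeplitz blocks) and
rows whose lag window would cross a trial boundary are discarded ("valid"
boundary condition). λ is optimized per channel on a log-spaced grid by
nested leave-one-out cross-validation over trials; prediction accuracy is
the Pearson correlation between predicted and observed responses on the
held-out trial, averaged over outer folds.

Positive lag d means the stimulus sample at t−d influences the response at
t (stimulus precedes response); negative lags capture anticipatory weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


def default_lambda_grid(n: int = 21, lo_exp: float = -10, hi_exp: float = 10) -> np.ndarray:
    """Log-linearly spaced ridge penalties, default 21 points from 2⁻¹⁰ to 2¹⁰."""
    return 2.0 ** np.linspace(lo_exp, hi_exp, n)


def lag_indices(tmin_ms: float, tmax_ms: float, fs_hz: float) -> np.ndarray:
    """Inclusive sample-lag range floor(tmin·fs) … ceil(tmax·fs).

    At 128 Hz the conventional −150…450 ms window maps to lags −20…58,
    i.e. 79 delays.
    """
    if not tmin_ms < tmax_ms:
        raise ValueError("tmin_ms must be smaller than tmax_ms")
    d_min = int(np.floor(tmin_ms / 1000.0 * fs_hz))
    d_max = int(np.ceil(tmax_ms / 1000.0 * fs_hz))
    return np.arange(d_min, d_max + 1)


@dataclass
class LaggedDesign:
    """Valid-rows lagged feature matrix (T_valid × P·D)."""

    matrix: np.ndarray
    lag_samples: np.ndarray
    feature_names: list[str]
    fs_hz: float
    valid_start: int  # first included time index of the original grid
    valid_stop: int   # one past the last included time index

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.fs_hz

    @property
    def n_lags(self) -> int:
        return len(self.lag_samples)


def build_lagged_design(
    regressors: Mapping[str, np.ndarray],
    fs_hz: float,
    tmin_ms: float = -150.0,
    tmax_ms: float = 450.0,
) -> LaggedDesign:
    """Stack features over lags with the valid boundary condition.

    Column order is feature-major (all lags of feature 1, then feature 2,
    …). Valid rows are time points t with t−d inside the trial for every
    lag d, i.e. t ∈ [max(d_max, 0), T + min(d_min, 0)).
    """
    names = list(regressors)
    series = [np.asarray(regressors[k], dtype=float) for k in names]
    T = len(series[0])
    if any(len(s) != T for s in series):
        raise ValueError("all regressors must share the trial time grid")
    lags = lag_indices(tmin_ms, tmax_ms, fs_hz)
    start = max(int(lags[-1]), 0)
    stop = T + min(int(lags[0]), 0)
    if stop <= start:
        raise ValueError(
            f"trial of {T} samples shorter than the lag span {lags[-1] - lags[0]}"
        )
    X = np.empty((stop - start, len(names) * len(lags)))
    col = 0
    for s in series:
        for d in lags:
            X[:, col] = s[start - d : stop - d]
            col += 1
    return LaggedDesign(X, lags, names, fs_hz, start, stop)


@dataclass
class TRFKernel:
    """Estimated TRF weights per feature × lag × channel."""

    weights: np.ndarray  # (P, D, C)
    lambda_per_channel: np.ndarray  # (C,)
    lag_samples: np.ndarray
    feature_names: list[str]
    fs_hz: float

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.fs_hz


def ridge_fit(design: LaggedDesign, response: np.ndarray, lam: float) -> np.ndarray:
    """Solve the regularized normal equations (XᵀX + λI) b = Xᵀy.

    ``response`` has the design's valid rows (1-D or T_valid × C). Uses a
    symmetric positive-definite (Cholesky) solve; λ=0 falls back to a
    least-squares solve and raises if the design is rank-deficient.
    Returns weights of shape (P·D,) or (P·D, C).
    """
    X = design.matrix
    y = np.asarray(response, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"response rows {y.shape[0]} != design rows {X.shape[0]}")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0.0:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design (rank {rank} < {X.shape[1]}); use lambda > 0"
            )
        return beta
    G = X.T @ X + lam * np.eye(X.shape[1])
    c, low = linalg.cho_factor(G, lower=True)
    return linalg.cho_solve((c, low), X.T @ y)


def predict(design: LaggedDesign, weights: np.ndarray) -> np.ndarray:
    """ŷ = X b over the design's valid rows."""
    if weights.shape[0] != design.matrix.shape[1]:
        raise ValueError(
            f"weight rows {weights.shape[0]} != design columns {design.matrix.shape[1]}"
        )
    return design.matrix @ weights


def pearson_r(yhat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; NaN where either series is constant."""
    yhat = np.atleast_2d(np.asarray(yhat, float).T).T
    y = np.atleast_2d(np.asarray(y, float).T).T
    a = yhat - yhat.mean(axis=0)
    b = y - y.mean(axis=0)
    na = np.sqrt((a**2).sum(axis=0))
    nb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r.squeeze()


@dataclass
class Trial:
    """One trial: EEG (channels × time) plus feature regressors on its grid."""

    eeg: np.ndarray
    regressors: dict[str, np.ndarray]
    fs_hz: float
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be channels x time")
        T = self.eeg.shape[1]
        for k, v in self.regressors.items():
            v = np.asarray(v, dtype=float)
            if len(v) != T:
                raise ValueError(f"regressor {k!r} length {len(v)} != eeg time {T}")
            self.regressors[k] = v

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score along an axis; zero-variance slices are left at zero."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


@dataclass
class CVResult:
    """Leave-one-out prediction accuracies and selected penalties."""

    r_per_fold: np.ndarray  # (n_folds, C)
    optimal_lambda: np.ndarray  # (n_folds, C)
    lambda_grid: np.ndarray
    feature_names: list[str]

    @property
    def mean_r(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.r_per_fold, axis=0)


class _GramRidge:
    """Multi-λ multi-channel ridge from accumulated Gram matrices.

    Eigendecomposing G = Σᵢ XᵢᵀXᵢ once gives b̂(λ) = V diag(1/(w+λ)) Vᵀ h
    for every λ on the grid at negligible extra cost.
    """

    def __init__(self, G: np.ndarray, H: np.ndarray):
        self.w, self.V = np.linalg.eigh(G)
        self.VtH = self.V.T @ H  # (p, C)

    def solve(self, lam: float) -> np.ndarray:
        return self.V @ (self.VtH / (self.w + lam)[:, None])

    def solve_grid(self, lams: np.ndarray) -> np.ndarray:
        # (n_lam, p, C)
        return np.einsum(
            "qp,lpc->lqc", self.V, self.VtH[None] / (self.w[None, :, None] + np.asarray(lams)[:, None, None])
        )


def _trial_blocks(
    trials: Sequence[Trial],
    features: Sequence[str],
    tmin_ms: float,
    tmax_ms: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-trial Z-scored designs and valid-row responses."""
    Xs, Ys = [], []
    for tr in trials:
        missing = [f for f in features if f not in tr.regressors]
        if missing:
            raise KeyError(f"trial {tr.stimulus_id!r} lacks regressors {missing}")
        regs = {f: zscore(tr.regressors[f]) for f in features}
        d = build_lagged_design(regs, tr.fs_hz, tmin_ms, tmax_ms)
        y = zscore(tr.eeg, axis=1).T[d.valid_start : d.valid_stop]
        Xs.append(d.matrix)
        Ys.append(y)
    return Xs, Ys


def loo_crossval(
    trials: Sequence[Trial],
    features: Sequence[str],
    lambda_grid: np.ndarray | None = None,
    tmin_ms: float = -150.0,
    tmax_ms: float = 450.0,
    per_channel: bool = True,
) -> CVResult:
    """Nested leave-one-out cross-validation with per-channel λ selection.

    Outer loop holds out one trial; on the remaining training trials an
    inner leave-one-out selects, per channel, the λ with the highest mean
    inner-fold accuracy (ties resolve to the smallest λ). The kernel is
    then refit on all training trials at the selected λ and scored on the
    held-out trial by Pearson r per channel. ``per_channel=False`` selects
    a single λ maximizing the channel-mean inner accuracy.

    Features and EEG are Z-scored per trial before lagging, mirroring the
    preprocessing convention.
    """
    if len(trials) < 3:
        raise ValueError("leave-one-out CV needs at least 3 trials")
    lams = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    Xs, Ys = _trial_blocks(trials, features, tmin_ms, tmax_ms)
    n = len(trials)
    C = Ys[0].shape[1]
    Gs = [X.T @ X for X in Xs]
    Hs = [X.T @ Y for X, Y in zip(Xs, Ys)]
    G_all, H_all = sum(Gs), sum(Hs)

    r_folds = np.full((n, C), np.nan)
    lam_folds = np.full((n, C), np.nan)
    for k in range(n):
        train = [i for i in range(n) if i != k]
        # inner LOO over training trials: accuracy per lambda per channel
        acc = np.zeros((len(lams), C))
        counts = np.zeros((len(lams), C))
        for j in train:
            solver = _GramRidge(G_all - Gs[k] - Gs[j], H_all - Hs[k] - Hs[j])
            betas = solver.solve_grid(lams)  # (L, p, C)
            preds = np.einsum("tp,lpc->ltc", Xs[j], betas)
            for li in range(len(lams)):
                r = np.atleast_1d(pearson_r(preds[li], Ys[j]))
                ok = ~np.isnan(r)
                acc[li, ok] += r[ok]
                counts[li, ok] += 1
        with np.errstate(invalid="ignore"):
            acc = acc / counts
        acc = np.nan_to_num(acc, nan=-np.inf)
        if per_channel:
            opt_idx = np.argmax(acc, axis=0)  # first max → smallest lambda
        else:
            opt_idx = np.full(C, int(np.argmax(acc.mean(axis=1))))
        # refit on all training trials at the selected lambdas
        solver = _GramRidge(G_all - Gs[k], H_all - Hs[k])
        betas = solver.solve_grid(lams[np.unique(opt_idx)])
        lut = {li: pos for pos, li in enumerate(np.unique(opt_idx))}
        B = np.empty((Xs[k].shape[1], C))
        for c in range(C):
            B[:, c] = betas[lut[opt_idx[c]], :, c]
        r = np.atleast_1d(pearson_r(Xs[k] @ B, Ys[k]))
        r_folds[k] = r
        lam_folds[k] = lams[opt_idx]
        if np.any(np.isnan(r)):
            logger.info("fold %d: %d channel(s) with undefined accuracy", k,
                        int(np.isnan(r).sum()))
    return CVResult(r_folds, lam_folds, lams, list(features))


def train_trf(
    trials: Sequence[Trial],
    features: Sequence[str],
    lam: float | np.ndarray,
    tmin_ms: float = -150.0,
    tmax_ms: float = 450.0,
) -> TRFKernel:
    """Fit a TRF on all trials at a fixed (scalar or per-channel) λ."""
    Xs, Ys = _trial_blocks(trials, features, tmin_ms, tmax_ms)
    G = sum(X.T @ X for X in Xs)
    H = sum(X.T @ Y for X, Y in zip(Xs, Ys))
    C = Ys[0].shape[1]
    lams = np.broadcast_to(np.asarray(lam, dtype=float), (C,))
    solver = _GramRidge(G, H)
    uniq = np.unique(lams)
    betas = {u: solver.solve(u) for u in uniq}
    B = np.column_stack([betas[lams[c]][:, c] for c in range(C)])
    lags = lag_indices(tmin_ms, tmax_ms, trials[0].fs_hz)
    P, D = len(features), len(lags)
    return TRFKernel(B.reshape(P, D, C), lams.copy(), lags, list(features),
                     trials[0].fs_hz)
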