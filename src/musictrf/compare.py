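"""Nested model families and cluster-based permutation inference.

Feature encoding is inferred by comparing leave-one-out prediction
accuracies of nested TRF model families: if the added feature carries no
uniquely explained variance, the full model cannot beat the reduced one.
Per-channel paired t-statistics on the accuracy differences are
thresholded to form spatially connected channel clusters; each cluster's
summed t is compared against a Monte Carlo null of maximum cluster
statistics obtained by random sign-flips of participants (sampled with
replacement), which controls the family-wise error rate at the cluster
alpha. Cluster-mean accuracy differences get percentile bootstrap CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Nested model families: baseline envelope, rhythmic additions, tonal
#: additions covarying the rhythmic features.
MODEL_FAMILIES: dict[str, list[str]] = {
    "env": ["envelope"],
    "env+beat": ["envelope", "beat"],
    "env+meter": ["envelope", "strong", "middle", "weak"],
    "env+meter+clarity": ["envelope", "strong", "middle", "weak", "clarity"],
    "env+meter+stability": ["envelope", "strong", "middle", "weak", "stability"],
}

#: (comparison name, full family, reduced family). The envelope comparison
#: uses phase-randomized surrogate accuracies as the reduced model.
COMPARISONS: list[tuple[str, str, str]] = [
    ("envelope", "env", "env_surrogate"),
    ("beat", "env+beat", "env"),
    ("meter", "env+meter", "env+beat"),
    ("clarity", "env+meter+clarity", "env+meter"),
    ("stability", "env+meter+stability", "env+meter"),
]


@dataclass
class ChannelLayout:
    """Channel names, 2-D coordinates, and a symmetric adjacency relation."""

    names: list[str]
    positions: np.ndarray  # (C, 2)
    adjacency: np.ndarray  # (C, C) bool, symmetric, irreflexive

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.shape != (len(self.names),) * 2:
            raise ValueError("adjacency must be square over all channels")
        if np.any(A != A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A)):
            raise ValueError("adjacency must be irreflexive")
        self.adjacency = A
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.adjacency]


def grid_layout(n_rows: int, n_cols: int) -> ChannelLayout:
    """Regular grid with 4-neighborhood adjacency (synthetic scalp stand-in)."""
    names, pos = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            names.append(f"ch_r{r}c{c}")
            pos.append((float(c), float(r)))
    pos = np.asarray(pos)
    d = np.abs(pos[:, None, :] - pos[None, :, :]).sum(axis=2)
    A = d == 1.0
    return ChannelLayout(names, pos, A)


def layout_from_positions(
    names: list[str], positions: np.ndarray, distance_threshold: float
) -> ChannelLayout:
    """Distance-threshold adjacency for measured channel coordinates."""
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    A = (d > 0) & (d <= distance_threshold)
    return ChannelLayout(list(names), pos, A)


def accuracy_difference(full: np.ndarray, reduced: np.ndarray) -> np.ndarray:
    """Per-participant per-channel accuracy difference r_full − r_reduced."""
    full = np.asarray(full, dtype=float)
    reduced = np.asarray(reduced, dtype=float)
    if full.shape != reduced.shape:
        raise ValueError(f"shape mismatch {full.shape} vs {reduced.shape}")
    return full - reduced


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t per channel vs 0; zero-variance channels get t = 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    t[sd == 0] = 0.0
    return t


def _clusters_from_mask(mask: np.ndarray, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of the suprathreshold channel set (BFS)."""
    seen = np.zeros(len(mask), dtype=bool)
    clusters = []
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in neighbors[node]:
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        clusters.append(np.sort(np.array(comp)))
    return clusters


def _max_cluster_sum(t: np.ndarray, t_crit: float, neighbors: list[np.ndarray]) -> float:
    mask = t > t_crit
    if not mask.any():
        return 0.0
    best = 0.0
    for comp in _clusters_from_mask(mask, neighbors):
        best = max(best, float(t[comp].sum()))
    return best


@dataclass
class ClusterTestResult:
    clusters: list[np.ndarray]
    sum_t: np.ndarray
    p_values: np.ndarray
    t_obs: np.ndarray
    n_permutations: int
    alpha_forming: float
    alpha_fwer: float
    bootstrap_ci: list[tuple[float, float]] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha_fwer

    def min_p(self) -> float:
        return float(self.p_values.min()) if len(self.p_values) else 1.0


def cluster_permutation_test(
    diffs: np.ndarray,
    layout: ChannelLayout,
    n_permutations: int = 10_000,
    alpha_forming: float = 0.05,
    alpha_fwer: float = 0.05,
    tail: str = "greater",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Cluster-based Monte Carlo permutation test on accuracy differences.

    ``diffs`` is participants × channels. The default tail is one-sided
    (full > reduced), matching the nested-model logic that the added
    feature can only add predictive accuracy; ``tail='two-sided'`` forms
    positive and negative clusters at the split alpha. The null is built
    from independently sampled participant sign-flip assignments
    (permutations with replacement); cluster p-values use the Monte Carlo
    convention (1 + #{null ≥ obs}) / (n_permutations + 1), so the smallest
    attainable p is 1/(n_permutations + 1).
    """
    diffs = np.asarray(diffs, dtype=float)
    n, C = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if C != layout.n_channels:
        raise ValueError(f"layout has {layout.n_channels} channels, diffs {C}")
    if n_permutations < 100:
        warnings.warn(f"only {n_permutations} permutations: p-values are coarse")
    if rng is None:
        rng = np.random.default_rng(seed)
    df = n - 1
    if tail == "greater":
        t_crit = stats.t.ppf(1.0 - alpha_forming, df)
        signed = 1.0
    elif tail == "two-sided":
        t_crit = stats.t.ppf(1.0 - alpha_forming / 2.0, df)
        signed = 1.0
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")

    neighbors = layout.neighbor_lists()
    t_obs = _paired_t(diffs)

    def observed_clusters(t: np.ndarray) -> tuple[list[np.ndarray], list[float]]:
        cl = _clusters_from_mask(t > t_crit, neighbors)
        sums = [float(t[c].sum()) for c in cl]
        if tail == "two-sided":
            for c in _clusters_from_mask(-t > t_crit, neighbors):
                cl.append(c)
                sums.append(float(t[c].sum()))
        return cl, sums

    clusters, sums = observed_clusters(t_obs * signed)

    # vectorized permutation t-statistics from sign-flipped differences
    signs = rng.integers(0, 2, size=(n_permutations, n)) * 2.0 - 1.0
    M = signs @ diffs / n
    msq = (diffs**2).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(np.maximum(msq[None, :] - M**2, 0.0) * n / df)
        t_perm = M / (sd / np.sqrt(n))
    t_perm[~np.isfinite(t_perm)] = 0.0

    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        m = _max_cluster_sum(t_perm[i], t_crit, neighbors)
        if tail == "two-sided":
            m = max(m, _max_cluster_sum(-t_perm[i], t_crit, neighbors))
        null_max[i] = m

    sums_arr = np.asarray(sums)
    p = np.array(
        [(1 + np.sum(null_max >= abs(s))) / (n_permutations + 1) for s in sums_arr]
    )
    return ClusterTestResult(
        clusters, sums_arr, p, t_obs, n_permutations, alpha_forming, alpha_fwer
    )


def bootstrap_cluster_ci(
    diffs: np.ndarray,
    cluster: np.ndarray,
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the cluster-mean accuracy difference.

    Participants are resampled with replacement; the statistic is the mean
    over resampled participants of each participant's cluster-mean diff.
    """
    diffs = np.asarray(diffs, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    if len(cluster) == 0:
        raise ValueError("cluster is empty")
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants to bootstrap")
    if rng is None:
        rng = np.random.default_rng(seed)
    per_subject = diffs[:, cluster].mean(axis=1)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = per_subject[idx].mean(axis=1)
    lo = (1.0 - ci) / 2.0
    return float(np.quantile(boots, lo)), float(np.quantile(boots, 1.0 - lo))


@dataclass
class ComparisonResult:
    name: str
    full: str
    reduced: str
    test: ClusterTestResult
    cluster_mean_r_full: list[float]
    cluster_mean_r_reduced: list[float]


def run_comparison_suite(
    accuracies: dict[str, np.ndarray],
    layout: ChannelLayout,
    n_permutations: int = 10_000,
    n_boot: int = 10_000,
    alpha_forming: float = 0.05,
    alpha_fwer: float = 0.05,
    seed: int | None = None,
    comparisons: list[tuple[str, str, str]] | None = None,
) -> dict[str, ComparisonResult]:
    """Run the five nested comparisons on participant-level accuracy maps.

    ``accuracies`` maps family name → participants × channels mean CV
    accuracy; an ``env_surrogate`` entry (accuracies averaged over the
    phase-randomization repetitions) serves as the reduced model of the
    envelope-tracking control comparison.
    """
    comps = COMPARISONS if comparisons is None else comparisons
    needed = {f for _, a, b in comps for f in (a, b)}
    missing = sorted(needed - set(accuracies))
    if missing:
        raise KeyError(f"missing model families: {missing}")
    rng = np.random.default_rng(seed)
    report: dict[str, ComparisonResult] = {}
    for name, full, reduced in comps:
        diffs = accuracy_difference(accuracies[full], accuracies[reduced])
        test = cluster_permutation_test(
            diffs, layout, n_permutations, alpha_forming, alpha_fwer, rng=rng
        )
        test.bootstrap_ci = [
            bootstrap_cluster_ci(diffs, c, n_boot, rng=rng) for c in test.clusters
        ]
        report[name] = ComparisonResult(
            name,
            full,
            reduced,
            test,
            [float(accuracies[full][:, c].mean()) for c in test.clusters],
            [float(accuracies[reduced][:, c].mean()) for c in test.clusters],
        )
    return report
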