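"""Network-state detection: cluster time windows by the similarity of their
connectivity configuration, via modularity maximization with a Louvain-like
greedy optimizer, consensus over repeated optimizations, resolution (gamma)
tuning by partition reliability, and retention of the three longest states.

The similarity graph is the T x T Pearson correlation matrix between
configuration vectors. Before modularity maximization negative similarities
are set to zero and the diagonal is zeroed — the Newman–Girvan null model is
defined for non-negative weights. Communities of windows ("states") need not
be temporally contiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .connectivity import ConfigurationMatrix
from .exceptions import ValidationError

__all__ = [
    "StatePartition",
    "configuration_similarity",
    "preprocess_similarity",
    "modularity_score",
    "louvain_optimize",
    "consensus_partition",
    "tune_gamma",
    "finalize_states",
]

PREPROCESSING_FLAGS = {"negatives_zeroed": True, "diagonal_zeroed": True}


@dataclass
class StatePartition:
    """Assignment of each time window to a network state.

    ``retained_states`` is populated by :func:`finalize_states`: the (at most
    3) largest states, relabeled 0, 1, 2 in order of median temporal
    occurrence.
    """

    assignment: np.ndarray  # int label per window
    Q: float
    gamma: float
    n_optimizations: int
    seed: int | None = None
    retained_states: list[int] | None = None
    converged: bool = True
    preprocessing: dict = field(default_factory=lambda: dict(PREPROCESSING_FLAGS))

    @property
    def n_windows(self) -> int:
        return len(self.assignment)

    def state_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.assignment, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# similarity


def configuration_similarity(cfg: ConfigurationMatrix | np.ndarray) -> np.ndarray:
    """T x T Pearson correlation between configuration vectors.

    Zero-variance configuration columns get similarity 0 to every other
    window (with a warning); the diagonal is exactly 1.
    """
    values = cfg.values if isinstance(cfg, ConfigurationMatrix) else np.asarray(cfg, float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValidationError("need a (n_pairs, T) matrix with T >= 2")
    sd = values.std(axis=0)
    dead = sd < 1e-14
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(values, rowvar=False)
    if dead.any():
        warnings.warn(
            f"zero-variance configuration columns {np.flatnonzero(dead).tolist()}: similarity set to 0"
        )
        S[dead, :] = 0.0
        S[:, dead] = 0.0
    S = np.clip(S, -1.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def preprocess_similarity(S: np.ndarray) -> np.ndarray:
    """Zero negative similarities and the diagonal (idempotent)."""
    W = np.array(S, dtype=float, copy=True)
    W[W < 0] = 0.0
    np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# modularity


def modularity_score(S: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman–Girvan modularity Q of a window partition.

    Q = (1/2m) sum_{k,l} [W_kl - gamma s_k s_l / (2m)] delta(g_k, g_l)
    on the preprocessed similarity W (applied internally; idempotent).
    """
    W = preprocess_similarity(S)
    labels = np.asarray(labels)
    if labels.shape[0] != W.shape[0]:
        raise ValidationError("labels length does not match similarity size")
    two_m = W.sum()
    if two_m <= 0:
        return 0.0
    s = W.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        q += W[np.ix_(idx, idx)].sum() - gamma * s[idx].sum() ** 2 / two_m
    return float(q / two_m)


# ---------------------------------------------------------------------------
# Louvain on a generalized gain matrix


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ints in order of first occurrence."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen))
    return out


def _local_move(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy node moves maximizing the within-community sum of B.

    Nodes are visited in seeded random order; each node moves to the
    community with the best positive gain (ties to the first candidate),
    where detaching into a fresh singleton community counts as a candidate —
    without that escape move the greedy pass cannot split a community that
    early merges formed badly.
    """
    n = B.shape[0]
    comm = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            conn = np.bincount(comm, weights=B[i], minlength=n + 1)
            conn[comm[i]] -= B[i, i]  # self-loop always stays with i
            empty = np.flatnonzero(np.bincount(comm, minlength=n + 1) == 0)[0]
            conn[empty] = 0.0  # gain of detaching into a new singleton
            best = int(np.argmax(conn))
            if conn[best] > conn[comm[i]] + 1e-12:
                comm[i] = best
                improved = True
    return _canonical(comm)


def _louvain_gain(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Full Louvain (local moving + aggregation) on symmetric gain matrix B."""
    node_comm = np.arange(B.shape[0])
    level = B
    while True:
        comm = _local_move(level, rng)
        n_comm = comm.max() + 1
        if n_comm == level.shape[0]:
            break
        node_comm = comm[node_comm]
        onehot = np.eye(n_comm)[comm]
        level = onehot.T @ level @ onehot
    return _canonical(node_comm)


def louvain_optimize(
    S: np.ndarray, gamma: float = 1.0, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """One greedy modularity optimization of the window-similarity graph.

    Returns an integer label per window. The node visit order is randomized
    by ``seed``; different seeds explore different local maxima of Q.
    """
    W = preprocess_similarity(S)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    two_m = W.sum()
    if two_m <= 0:
        return np.arange(W.shape[0])
    s = W.sum(axis=1)
    B = W - gamma * np.outer(s, s) / two_m
    return _louvain_gain(B, rng)


# ---------------------------------------------------------------------------
# consensus


def _association_matrix(runs: list[np.ndarray]) -> np.ndarray:
    T = len(runs[0])
    D = np.zeros((T, T))
    for lab in runs:
        D += lab[:, None] == lab[None, :]
    D /= len(runs)
    np.fill_diagonal(D, 0.0)
    return D


def consensus_partition(
    S: np.ndarray,
    gamma: float = 1.0,
    n_optimizations: int = 1000,
    seed: int | None = None,
    max_iter: int = 10,
) -> StatePartition:
    """Consensus over repeated modularity optimizations.

    Runs ``n_optimizations`` seeded optimizations; if they disagree, the
    co-assignment (association) matrix is re-clustered with the same greedy
    engine under a permutation null (mean off-diagonal co-assignment),
    iterating until all runs agree or ``max_iter`` is hit (then the modal
    structure so far is returned with ``converged=False`` and a warning).
    """
    W = preprocess_similarity(S)
    rng = np.random.default_rng(seed)
    runs = [louvain_optimize(W, gamma, rng) for _ in range(n_optimizations)]
    converged = True
    for _ in range(max_iter):
        first = runs[0]
        if all(np.array_equal(first, r) for r in runs[1:]):
            break
        D = _association_matrix(runs)
        null = D.sum() / (D.shape[0] * (D.shape[0] - 1))
        B = D - null
        np.fill_diagonal(B, 0.0)
        runs = [_louvain_gain(B, rng) for _ in range(n_optimizations)]
    else:
        warnings.warn(f"consensus did not converge in {max_iter} iterations")
        converged = False
    labels = runs[0]
    return StatePartition(
        assignment=labels,
        Q=modularity_score(W, labels, gamma),
        gamma=float(gamma),
        n_optimizations=n_optimizations,
        seed=seed,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# gamma tuning


def _degenerate(labels: np.ndarray) -> bool:
    k = len(np.unique(labels))
    return k == 1 or k == len(labels)


def partition_reliability(runs: list[np.ndarray]) -> float:
    """Mean pairwise adjusted Rand index across repeated optimizations."""
    pairs = list(combinations(range(len(runs)), 2))
    return float(np.mean([adjusted_rand_score(runs[a], runs[b]) for a, b in pairs]))


def tune_gamma(
    S: np.ndarray,
    gamma_grid: np.ndarray | list[float] | None = None,
    n_reps: int = 20,
    seed: int | None = None,
) -> float:
    """Select the structural resolution gamma maximizing partition reliability.

    Reliability at each gamma is the mean pairwise adjusted Rand index of
    ``n_reps`` independent optimizations. Ties break toward gamma = 1. If
    every gamma yields only degenerate partitions (all-singleton or
    all-in-one), gamma = 1 is returned with a warning.
    """
    if gamma_grid is None:
        gamma_grid = np.arange(0.5, 1.5001, 0.05)
    gamma_grid = np.asarray(list(gamma_grid), dtype=float)
    if gamma_grid.size == 0:
        raise ValidationError("gamma_grid is empty")
    rng = np.random.default_rng(seed)
    W = preprocess_similarity(S)
    scores = np.full(gamma_grid.size, -np.inf)
    for g_idx, gamma in enumerate(gamma_grid):
        runs = [louvain_optimize(W, gamma, rng) for _ in range(n_reps)]
        if all(_degenerate(r) for r in runs):
            continue
        scores[g_idx] = partition_reliability(runs)
    if np.all(np.isinf(scores)):
        warnings.warn("all gammas gave degenerate partitions; returning gamma=1.0")
        return 1.0
    best = scores.max()
    candidates = gamma_grid[scores >= best - 1e-12]
    return float(candidates[np.argmin(np.abs(candidates - 1.0))])


# ---------------------------------------------------------------------------
# retention / relabeling


def finalize_states(partition: StatePartition, n_retain: int = 3) -> StatePartition:
    """Retain the ``n_retain`` largest states and relabel by temporal order.

    State size is the number of member windows (not necessarily contiguous).
    Retained states are relabeled 0..n_retain-1 by the median window index of
    their members (0 = earliest); the remaining states follow, also in median
    order. If fewer than ``n_retain`` states exist, all are retained with a
    warning.
    """
    labels = np.asarray(partition.assignment)
    uniq = np.unique(labels)
    sizes = {lab: int((labels == lab).sum()) for lab in uniq}
    medians = {lab: float(np.median(np.flatnonzero(labels == lab))) for lab in uniq}
    by_size = sorted(uniq, key=lambda lab: (-sizes[lab], medians[lab]))
    kept = by_size[:n_retain]
    rest = by_size[n_retain:]
    if len(uniq) < n_retain:
        warnings.warn(f"only {len(uniq)} states found; retaining all")
    order = sorted(kept, key=lambda lab: medians[lab]) + sorted(rest, key=lambda lab: medians[lab])
    mapping = {lab: new for new, lab in enumerate(order)}
    new_labels = np.array([mapping[lab] for lab in labels], dtype=int)
    return replace(
        partition,
        assignment=new_labels,
        retained_states=list(range(len(kept))),
    )
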