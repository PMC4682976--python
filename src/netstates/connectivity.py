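"""Window-wise functional connectivity by magnitude-normalized
cross-correlation, and the dynamic-network / configuration-matrix containers.

For each window and channel pair (i, j) the connection weight is

    A[i, j] = max_{|tau| <= tau_max} | sum_t x_i(t) x_j(t + tau) | / (L s_i s_j)

with L the window length in samples and s the full-window standard
deviations (biased normalization, which bounds the value in [0, 1] by
Cauchy–Schwarz). The lag search window tau_max defaults to 0.25 s, a bound
on physiological conduction delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft

from .exceptions import ValidationError
from .preprocess import WindowedEpoch

__all__ = [
    "DynamicNetwork",
    "ConfigurationMatrix",
    "window_connectivity",
    "build_dynamic_network",
    "to_configuration_matrix",
    "configuration_to_adjacency",
]


@dataclass
class DynamicNetwork:
    """T symmetric N x N weighted adjacency matrices, one per window."""

    adjacency: np.ndarray  # (T, N, N), entries in [0, 1], zero diagonal
    channel_ids: list[str]
    window_starts_s: np.ndarray
    tau_max_s: float
    label: str = ""

    @property
    def n_windows(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[1]


@dataclass
class ConfigurationMatrix:
    """N(N-1)/2 connection weights x T windows.

    Row k corresponds to ``pairs[k]``, the row-major upper-triangle ordering
    ``(0,1), (0,2), ..., (0,N-1), (1,2), ...`` of unordered channel pairs.
    """

    values: np.ndarray  # (n_pairs, T)
    channel_ids: list[str]
    window_starts_s: np.ndarray = field(default=None)
    label: str = ""

    def __post_init__(self):
        n = len(self.channel_ids)
        if self.values.shape[0] != n * (n - 1) // 2:
            raise ValidationError(
                f"{self.values.shape[0]} rows != N(N-1)/2 for N={n} channels"
            )
        if self.window_starts_s is None:
            self.window_starts_s = np.arange(self.values.shape[1], dtype=float)

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_channels, k=1)
        return list(zip(iu[0].tolist(), iu[1].tolist()))

    def pair_labels(self) -> list[str]:
        ids = self.channel_ids
        return [f"{ids[i]}--{ids[j]}" for i, j in self.pairs]


def window_connectivity(window: np.ndarray, max_lag: int) -> np.ndarray:
    """Connectivity matrix of one (pre-processed) window.

    ``max_lag`` is in samples; ``max_lag = 0`` reduces to the absolute
    zero-lag Pearson correlation. Channels with zero variance get all-zero
    connections (with a warning).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("window must be channels x samples with >= 2 channels")
    n, L = x.shape
    if not 0 <= max_lag < L:
        raise ValidationError(f"max_lag {max_lag} outside [0, {L - 1}]")
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    dead = sd < 1e-14
    if dead.any():
        warnings.warn(f"zero-variance channels {np.flatnonzero(dead).tolist()}: connections set to 0")
        sd = np.where(dead, 1.0, sd)

    nfft = spfft.next_fast_len(2 * L - 1)
    F = spfft.rfft(x, nfft, axis=1)
    adj = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    # cross-correlate every pair against channel i in one inverse transform batch
    for i in range(n - 1):
        cc = spfft.irfft(F[i][None, :] * np.conj(F[i + 1 :]), nfft, axis=1)
        # cc[:, k] = sum_t x_i[t] x_j[t - k]; negative lags wrap to the end
        tail = cc[:, nfft - max_lag :] if max_lag > 0 else cc[:, :0]
        best = np.abs(np.concatenate([cc[:, : max_lag + 1], tail], axis=1)).max(axis=1)
        adj[i, i + 1 :] = best / (L * sd[i] * sd[i + 1 :])
    adj = adj + adj.T
    if dead.any():
        adj[dead, :] = 0.0
        adj[:, dead] = 0.0
    np.clip(adj, 0.0, 1.0, out=adj)
    return adj


def build_dynamic_network(wep: WindowedEpoch, tau_max_s: float = 0.25) -> DynamicNetwork:
    """Per-window connectivity for a whole epoch, in temporal order.

    All connection weights are retained; no thresholding is applied.
    """
    if wep.n_windows < 2:
        raise ValidationError("need at least 2 windows")
    max_lag = int(round(tau_max_s * wep.fs))
    adj = np.stack([window_connectivity(w, max_lag) for w in wep.windows])
    return DynamicNetwork(
        adjacency=adj,
        channel_ids=list(wep.channel_ids),
        window_starts_s=wep.window_starts_s,
        tau_max_s=tau_max_s,
        label=wep.label,
    )


def to_configuration_matrix(net: DynamicNetwork) -> ConfigurationMatrix:
    """Vectorize each adjacency's upper triangle into a (N(N-1)/2, T) matrix."""
    iu = np.triu_indices(net.n_channels, k=1)
    values = net.adjacency[:, iu[0], iu[1]].T.copy()
    return ConfigurationMatrix(
        values=values,
        channel_ids=list(net.channel_ids),
        window_starts_s=net.window_starts_s,
        label=net.label,
    )


def configuration_to_adjacency(cfg: ConfigurationMatrix) -> np.ndarray:
    """Inverse of :func:`to_configuration_matrix` (lossless round trip)."""
    n, t = cfg.n_channels, cfg.n_windows
    adj = np.zeros((t, n, n))
    iu = np.triu_indices(n, k=1)
    adj[:, iu[0], iu[1]] = cfg.values.T
    adj[:, iu[1], iu[0]] = cfg.values.T
    return adj
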