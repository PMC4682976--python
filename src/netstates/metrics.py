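"""Per-epoch and per-state statistics: flexibility, state duration fractions,
connection density, and the connection type index with event-level
strong/weak percentile thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConfigurationMatrix
from .exceptions import ValidationError
from .states import StatePartition

__all__ = [
    "TypeThresholds",
    "StateMetrics",
    "flexibility",
    "duration_fractions",
    "connection_density",
    "type_thresholds",
    "connection_type_index",
    "state_metrics",
]


def _values(cfg) -> np.ndarray:
    return cfg.values if isinstance(cfg, ConfigurationMatrix) else np.asarray(cfg, float)


@dataclass
class TypeThresholds:
    """Event-level strong/weak cutoffs from the pooled strength distribution
    of both epochs (all connections, all windows)."""

    strong_cut: float
    weak_cut: float
    strong_pct: float = 95.0
    weak_pct: float = 5.0

    def __post_init__(self):
        if self.weak_cut > self.strong_cut:
            raise ValidationError("weak_cut exceeds strong_cut")


@dataclass
class StateMetrics:
    """Summary of one retained network state."""

    label: int
    n_windows: int
    duration_fraction: float
    density: float
    type_index: float


def flexibility(partition: StatePartition | np.ndarray) -> float:
    """Rate of state transitions: fraction of consecutive window pairs whose
    labels differ. Uses the full label sequence (all states, not only the
    retained ones)."""
    labels = partition.assignment if isinstance(partition, StatePartition) else np.asarray(partition)
    if len(labels) < 2:
        raise ValidationError("flexibility undefined for fewer than 2 windows")
    return float(np.mean(labels[1:] != labels[:-1]))


def duration_fractions(partition: StatePartition | np.ndarray) -> pd.Series:
    """Fraction of epoch duration spent in each state, ordered by size
    descending. Fractions sum to 1 over all states of the epoch."""
    labels = partition.assignment if isinstance(partition, StatePartition) else np.asarray(partition)
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return pd.Series(counts[order] / len(labels), index=uniq[order], name="duration_fraction")


def connection_density(cfg, state_windows) -> float:
    """Mean connection strength over all connections and all windows of a state."""
    values = _values(cfg)
    idx = np.asarray(state_windows, dtype=int)
    if idx.size == 0:
        raise ValidationError("state has no windows")
    return float(values[:, idx].mean())


def type_thresholds(
    cfg_preseizure,
    cfg_seizure,
    strong_pct: float = 95.0,
    weak_pct: float = 5.0,
) -> TypeThresholds:
    """Percentile cutoffs from the pooled pre-seizure + seizure distribution
    (linear-interpolation percentiles)."""
    pooled = np.concatenate([_values(cfg_preseizure).ravel(), _values(cfg_seizure).ravel()])
    if pooled.size < 20:
        raise ValidationError(f"only {pooled.size} pooled connection values; need >= 20")
    weak_cut, strong_cut = np.percentile(pooled, [weak_pct, strong_pct])
    return TypeThresholds(
        strong_cut=float(strong_cut),
        weak_cut=float(weak_cut),
        strong_pct=strong_pct,
        weak_pct=weak_pct,
    )


def connection_type_index(cfg, state_windows, thresholds: TypeThresholds) -> float:
    """B = (C_s - C_w) / (C_s + C_w) in [-1, 1].

    C_s (C_w) counts connection-window instances strictly above the strong
    (strictly below the weak) cutoff across the state's windows; +1 means all
    typed connections are strong, -1 all weak. Mid-range connections do not
    enter. Returns NaN (with a warning) when no connection is typed.
    """
    values = _values(cfg)
    idx = np.asarray(state_windows, dtype=int)
    sub = values[:, idx]
    c_s = int((sub > thresholds.strong_cut).sum())
    c_w = int((sub < thresholds.weak_cut).sum())
    if c_s + c_w == 0:
        warnings.warn("no strong or weak connections in state; type index undefined")
        return float("nan")
    return float((c_s - c_w) / (c_s + c_w))


def state_metrics(
    cfg, partition: StatePartition, thresholds: TypeThresholds
) -> list[StateMetrics]:
    """Density, duration fraction and type index for each retained state."""
    if partition.retained_states is None:
        raise ValidationError("run finalize_states before computing state metrics")
    out = []
    for lab in partition.retained_states:
        windows = np.flatnonzero(partition.assignment == lab)
        out.append(
            StateMetrics(
                label=int(lab),
                n_windows=int(windows.size),
                duration_fraction=float(windows.size / partition.n_windows),
                density=connection_density(cfg, windows),
                type_index=connection_type_index(cfg, windows, thresholds),
            )
        )
    return out
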