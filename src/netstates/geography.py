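"""Spatial analyses of network states relative to the seizure-onset zone
(SOZ) and to electrode-grid geometry: connection classes by SOZ membership,
per-class strengths, ROC/AUC for identifying SOZ-SOZ connections with a
sensor-relabeling permutation null, and the within-grid length–strength
Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

from .connectivity import ConfigurationMatrix
from .exceptions import ValidationError
from .simulate import SensorMap

__all__ = [
    "CLASS_LABELS",
    "RocResult",
    "TopographyResult",
    "classify_pairs",
    "strength_by_class",
    "soz_auc",
    "auc_null",
    "length_strength_correlation",
]

CLASS_LABELS = ("SOZ-SOZ", "SOZ-OUT", "OUT-OUT")


def _values(cfg) -> np.ndarray:
    return cfg.values if isinstance(cfg, ConfigurationMatrix) else np.asarray(cfg, float)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


@dataclass
class RocResult:
    """AUC for predicting SOZ-SOZ connections, with its permutation null."""

    auc: float
    null_ci: tuple[float, float]
    significant: bool
    n_permutations: int
    seed: int | None

    def __post_init__(self):
        lo, hi = self.null_ci
        if lo > hi:
            raise ValidationError("null CI bounds out of order")


@dataclass
class TopographyResult:
    """Mean per-window Spearman correlation between within-grid connection
    length (mm) and strength over a state's windows."""

    mean_rho: float
    n_windows: int
    n_windows_used: int
    n_pairs: int


def classify_pairs(sensors: SensorMap) -> np.ndarray:
    """Class of every unordered channel pair (upper-triangle order):
    SOZ-SOZ if both endpoints are flagged, OUT-OUT if neither, else SOZ-OUT."""
    soz = sensors.soz
    a, b = _pair_indices(sensors.n_channels)
    n_soz_ends = soz[a].astype(int) + soz[b].astype(int)
    return np.asarray(CLASS_LABELS)[2 - n_soz_ends]


def strength_by_class(cfg, state_windows, classes: np.ndarray) -> dict[str, float]:
    """Mean strength per geographic class over the state's windows.

    An absent class is reported as NaN.
    """
    values = _values(cfg)
    idx = np.asarray(state_windows, dtype=int)
    classes = np.asarray(classes)
    if classes.shape[0] != values.shape[0]:
        raise ValidationError("classes length does not match number of pairs")
    out = {}
    for lab in CLASS_LABELS:
        mask = classes == lab
        out[lab] = float(values[np.ix_(mask, idx)].mean()) if mask.any() else float("nan")
    return out


def soz_auc(strengths: np.ndarray, positives: np.ndarray) -> float:
    """AUC of ranking connections by strength with SOZ-SOZ as positives.

    Mann–Whitney formulation via midranks, so ties get half credit.
    """
    strengths = np.asarray(strengths, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("need at least one positive and one negative connection")
    ranks = rankdata(strengths)
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_null(
    strengths: np.ndarray,
    soz_flags: np.ndarray,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> RocResult:
    """Permutation null for the SOZ-SOZ AUC.

    Each permutation re-assigns the same number of sensors to the SOZ
    uniformly at random without replacement, re-derives the SOZ-SOZ pairs and
    recomputes the AUC; the null CI is the empirical 2.5/97.5 percentile band
    and significance means observed AUC above its upper bound. Permuting
    sensor labels (not pair labels) preserves the dependence among pairs
    sharing a sensor.
    """
    strengths = np.asarray(strengths, dtype=float)
    soz = np.asarray(soz_flags, dtype=bool)
    n = soz.size
    n_soz = int(soz.sum())
    if n_soz < 2:
        raise ValidationError("need >= 2 SOZ sensors to form SOZ-SOZ pairs")
    if n_soz >= n:
        raise ValidationError("all sensors in SOZ: no negative class")
    a, b = _pair_indices(n)
    if strengths.size != a.size:
        raise ValidationError("strengths length does not match N(N-1)/2 pairs")
    observed = soz_auc(strengths, soz[a] & soz[b])

    rng = np.random.default_rng(seed)
    ranks = rankdata(strengths)
    # membership matrix: each row is a random SOZ assignment of size n_soz
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    member = np.zeros((n_permutations, n), dtype=bool)
    np.put_along_axis(member, order[:, :n_soz], True, axis=1)
    pos = member[:, a] & member[:, b]  # (n_permutations, n_pairs)
    n_pos = n_soz * (n_soz - 1) // 2
    n_neg = a.size - n_pos
    u = pos @ ranks - n_pos * (n_pos + 1) / 2.0
    null_aucs = u / (n_pos * n_neg)
    lo, hi = np.percentile(null_aucs, [2.5, 97.5])
    return RocResult(
        auc=observed,
        null_ci=(float(lo), float(hi)),
        significant=bool(observed > hi),
        n_permutations=n_permutations,
        seed=seed,
    )


def length_strength_correlation(cfg, state_windows, sensors: SensorMap) -> TopographyResult:
    """Mean Spearman rho between connection length and strength.

    Only pairs whose two endpoints sit on the same electrode grid enter (so
    inter-contact spacing is uniform); rho is computed per window with
    midrank tie handling and averaged over the state's windows. Windows with
    zero strength variance are skipped with a warning.
    """
    values = _values(cfg)
    idx = np.asarray(state_windows, dtype=int)
    d = sensors.distances_mm()
    a, b = _pair_indices(sensors.n_channels)
    if values.shape[0] != a.size:
        raise ValidationError("configuration rows do not match sensor-map pairs")
    lengths = d[a, b]
    within = ~np.isnan(lengths)
    if within.sum() < 3:
        raise ValidationError("need >= 3 within-grid pairs for topography")
    lengths = lengths[within]
    rhos = []
    skipped = 0
    for t in idx:
        w = values[within, t]
        if w.std() < 1e-14:
            skipped += 1
            continue
        rhos.append(spearmanr(lengths, w).statistic)
    if skipped:
        warnings.warn(f"{skipped} windows with zero strength variance skipped")
    mean_rho = float(np.mean(rhos)) if rhos else float("nan")
    return TopographyResult(
        mean_rho=mean_rho,
        n_windows=int(idx.size),
        n_windows_used=len(rhos),
        n_pairs=int(within.sum()),
    )
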