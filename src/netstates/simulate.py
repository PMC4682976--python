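"""Synthetic multichannel recordings with planted network structure.

Electrocorticography-like test signals are built from a shared-latent-source
mixing model: in each 1 s window the channels are linear mixtures of common
Gaussian sources such that the expected pairwise correlation equals a planted
coupling matrix. The active coupling matrix switches between a small set of
latent "states" on a scripted schedule aligned to window boundaries, so the
ground-truth state label of every analysis window is unambiguous. On top of
the coupled signal each channel receives 1/f^alpha background noise and a
60 Hz line-noise sinusoid.

Three planted features mirror the statistical structure the downstream
pipeline is designed to detect:

* a designated sensor subset (a seizure-onset-zone analogue) whose
  within-subset coupling is multiplicatively boosted,
* coupling that decays exponentially with physical inter-sensor distance on
  an electrode grid,
* schedules with many short weak-coupling states ("pre-seizure") versus few
  long strong-coupling states ("seizure").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "SensorMap",
    "SimulationSpec",
    "RecordingEpoch",
    "generate_sensor_grid",
    "block_coupling",
    "effective_coupling",
    "window_labels",
    "simulate_epoch",
    "make_event",
    "planted_state_specs",
    "paper_regime_specs",
]

EPOCH_LABELS = ("pre-seizure", "seizure")

_SENSOR_COLUMNS = ["channel_id", "soz", "grid_id", "grid_row", "grid_col", "spacing_mm"]


class SensorMap:
    """Per-channel metadata: SOZ flag, grid membership, 2-D coordinates.

    Wraps a :class:`pandas.DataFrame` with columns ``channel_id`` (str),
    ``soz`` (bool), ``grid_id`` (str, NaN for off-grid contacts),
    ``grid_row``/``grid_col`` (grid indices, NaN off-grid) and ``spacing_mm``
    (inter-contact spacing, mm). Row order defines the channel order used
    by every adjacency and configuration matrix.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _SENSOR_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"sensor table missing columns: {missing}")
        frame = frame.reset_index(drop=True).assign(
            channel_id=frame["channel_id"].astype(str).values,
            soz=frame["soz"].astype(bool).values,
            grid_id=frame["grid_id"].astype("string").values,
            grid_row=frame["grid_row"].astype("float64").values,
            grid_col=frame["grid_col"].astype("float64").values,
            spacing_mm=frame["spacing_mm"].astype("float64").values,
        )
        if frame["channel_id"].duplicated().any():
            raise ValidationError("duplicate channel_id in sensor table")
        if (frame["spacing_mm"] <= 0).any():
            raise ValidationError("spacing_mm must be positive")
        on_grid = frame["grid_id"].notna()
        dup = frame.loc[on_grid, ["grid_id", "grid_row", "grid_col"]].duplicated()
        if dup.any():
            raise ValidationError("duplicate (grid_id, row, col) coordinates")
        self.frame = frame

    # -- basic accessors ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.frame)

    @property
    def channel_ids(self) -> list[str]:
        return self.frame["channel_id"].tolist()

    @property
    def soz(self) -> np.ndarray:
        return self.frame["soz"].to_numpy(dtype=bool)

    def positions_mm(self) -> np.ndarray:
        """(N, 2) physical coordinates; NaN for off-grid channels."""
        pos = np.full((self.n_channels, 2), np.nan)
        on = self.frame["grid_id"].notna().to_numpy()
        rows = self.frame["grid_row"].to_numpy(dtype=float)
        cols = self.frame["grid_col"].to_numpy(dtype=float)
        spacing = self.frame["spacing_mm"].to_numpy(dtype=float)
        pos[on, 0] = cols[on] * spacing[on]
        pos[on, 1] = rows[on] * spacing[on]
        return pos

    def distances_mm(self) -> np.ndarray:
        """(N, N) Euclidean distances in mm; NaN across grids or off-grid."""
        pos = self.positions_mm()
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        on = self.frame["grid_id"].notna().to_numpy()
        grid = self.frame["grid_id"].fillna("").to_numpy(dtype=object)
        same = (grid[:, None] == grid[None, :]) & on[:, None] & on[None, :]
        d[~same] = np.nan
        np.fill_diagonal(d, 0.0)
        return d

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorMap":
        frame = pd.read_csv(path, dtype={"grid_id": "string"})
        frame["soz"] = frame["soz"].astype(bool)
        return cls(frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SensorMap) and self.frame.equals(other.frame)


def generate_sensor_grid(
    rows: int,
    cols: int,
    spacing_mm: float = 10.0,
    soz_block: tuple[tuple[int, int], tuple[int, int]] | None = None,
    grid_id: str = "grid0",
    prefix: str = "ch",
) -> SensorMap:
    """Build a regular ``rows x cols`` electrode grid.

    Parameters
    ----------
    soz_block
        Optional ``((row_lo, row_hi), (col_lo, col_hi))`` inclusive index
        ranges flagged as the seizure-onset-zone analogue.
    """
    if rows < 2 or cols < 2:
        raise ConfigurationError("grid needs at least 2 rows and 2 columns")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    soz = np.zeros(rows * cols, dtype=bool)
    if soz_block is not None:
        (r0, r1), (c0, c1) = soz_block
        if not (0 <= r0 <= r1 < rows and 0 <= c0 <= c1 < cols):
            raise ConfigurationError(f"soz_block {soz_block} outside {rows}x{cols} grid")
        soz = (rr >= r0) & (rr <= r1) & (cc >= c0) & (cc <= c1)
    frame = pd.DataFrame(
        {
            "channel_id": [f"{prefix}{i:02d}" for i in range(rows * cols)],
            "soz": soz,
            "grid_id": grid_id,
            "grid_row": rr,
            "grid_col": cc,
            "spacing_mm": spacing_mm,
        }
    )
    return SensorMap(frame)


# ---------------------------------------------------------------------------
# simulation spec


@dataclass
class SimulationSpec:
    """Generative parameters for one epoch of synthetic recording.

    ``state_schedule`` is an ordered list of ``(state_id, duration_s)``;
    durations must be whole seconds so that state changes align with the 1 s
    analysis windows and ground-truth window labels are exact.
    ``coupling_matrices`` maps each scheduled state id to a symmetric,
    zero-diagonal N x N matrix of target pairwise correlations in [0, 1].
    """

    sensors: SensorMap
    state_schedule: list[tuple[object, float]]
    coupling_matrices: dict
    fs: float = 512.0
    soz_boost: float = 1.0
    distance_decay_mm: float | None = None
    noise_alpha: float = 1.0
    noise_scale: float = 0.5
    line_amp_60hz: float = 0.5
    seed: int = 0

    def __post_init__(self):
        n = self.sensors.n_channels
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if not self.state_schedule:
            raise ConfigurationError("empty state schedule")
        for sid, dur in self.state_schedule:
            if dur <= 0:
                raise ConfigurationError("schedule durations must be > 0")
            if abs(dur - round(dur)) > 1e-9:
                raise ConfigurationError(
                    "schedule durations must be whole seconds (window-aligned)"
                )
            if sid not in self.coupling_matrices:
                raise ConfigurationError(f"schedule references undefined state_id {sid!r}")
        if self.total_duration_s < 2.0:
            raise ConfigurationError("schedule must cover at least 2 s (two 1 s windows)")
        for sid, mat in self.coupling_matrices.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, n):
                raise ConfigurationError(f"coupling matrix {sid!r} is not {n}x{n}")
            if not np.allclose(mat, mat.T):
                raise ConfigurationError(f"coupling matrix {sid!r} not symmetric")
            if np.any(np.diag(mat) != 0):
                raise ConfigurationError(f"coupling matrix {sid!r} has nonzero diagonal")
            if mat.min() < 0 or mat.max() > 1:
                raise ConfigurationError(f"coupling matrix {sid!r} outside [0, 1]")
        if self.soz_boost < 1:
            raise ConfigurationError("soz_boost must be >= 1")
        if self.distance_decay_mm is not None and self.distance_decay_mm <= 0:
            raise ConfigurationError("distance_decay_mm must be positive")

    @property
    def n_channels(self) -> int:
        return self.sensors.n_channels

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.state_schedule))

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=int(seed))


@dataclass
class RecordingEpoch:
    """A block of multichannel signal with sampling rate and epoch label."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    label: str
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a channels x time matrix")
        if np.isnan(self.samples).any():
            raise ValidationError("samples contain NaN")
        if self.label not in EPOCH_LABELS:
            raise ValidationError(f"label must be one of {EPOCH_LABELS}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError("channel_ids length does not match samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


# ---------------------------------------------------------------------------
# coupling construction


def block_coupling(
    n: int,
    n_blocks: int,
    within: float,
    between: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random block-structured coupling: channels are shuffled into
    ``n_blocks`` groups with ``within`` coupling inside and ``between``
    across groups."""
    groups = np.sort(rng.permutation(n) % n_blocks)
    groups = groups[rng.permutation(n)]
    same = groups[:, None] == groups[None, :]
    mat = np.where(same, within, between).astype(float)
    np.fill_diagonal(mat, 0.0)
    return mat


def effective_coupling(spec: SimulationSpec, state_id) -> np.ndarray:
    """Planted expected correlation for one state after the SOZ boost and
    distance attenuation. The boost multiplies within-SOZ entries *before*
    attenuation so the two knobs stay independent."""
    mat = np.asarray(spec.coupling_matrices[state_id], dtype=float).copy()
    soz = spec.sensors.soz
    soz_pair = np.outer(soz, soz)
    mat[soz_pair] *= spec.soz_boost
    if spec.distance_decay_mm is not None:
        d = spec.sensors.distances_mm()
        atten = np.exp(-d / spec.distance_decay_mm)
        atten[np.isnan(atten)] = 1.0  # off-grid pairs: no attenuation defined
        mat *= atten
    np.clip(mat, 0.0, 0.99, out=mat)
    np.fill_diagonal(mat, 0.0)
    return mat


def window_labels(spec: SimulationSpec) -> np.ndarray:
    """Ground-truth state id of each 1 s analysis window."""
    labels: list = []
    for sid, dur in spec.state_schedule:
        labels.extend([sid] * int(round(dur)))
    return np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# signal synthesis


def _mixing_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T ~ corr (PSD-projected, unit diagonal)."""
    r = corr.copy()
    np.fill_diagonal(r, 1.0)
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 1e-9, None)
    fac = v * np.sqrt(w)
    # re-normalize rows so each channel has unit variance after projection
    norms = np.sqrt((fac**2).sum(axis=1))
    return fac / norms[:, None]


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, alpha: float) -> np.ndarray:
    """1/f^alpha noise via spectral shaping, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_epoch(spec: SimulationSpec, label: str) -> RecordingEpoch:
    """Realize one epoch of synthetic signal from the latent-source model.

    Identical ``(spec, label)`` always yield bit-identical samples. Expected
    per-window correlation magnitude increases monotonically with the
    effective (boosted, attenuated) coupling entry of the active state.
    """
    if label not in EPOCH_LABELS:
        raise ValidationError(f"label must be one of {EPOCH_LABELS}")
    rng = np.random.default_rng([spec.seed, EPOCH_LABELS.index(label)])
    n = spec.n_channels
    win = int(round(spec.fs))
    labels = window_labels(spec)
    n_samples = win * len(labels)

    factors = {sid: _mixing_factor(effective_coupling(spec, sid)) for sid in spec.coupling_matrices}
    signal = np.empty((n, n_samples))
    for k, sid in enumerate(labels):
        z = rng.standard_normal((n, win))
        signal[:, k * win : (k + 1) * win] = factors[sid] @ z

    out = signal
    if spec.noise_scale > 0:
        out = out + spec.noise_scale * _pink_noise(rng, n, n_samples, spec.noise_alpha)
    if spec.line_amp_60hz > 0:
        t = np.arange(n_samples) / spec.fs
        phases = rng.uniform(0, 2 * np.pi, size=n)
        out = out + spec.line_amp_60hz * np.sin(
            2 * np.pi * 60.0 * t[None, :] + phases[:, None]
        )
    return RecordingEpoch(out, fs=spec.fs, label=label, channel_ids=spec.sensors.channel_ids)


def make_event(
    spec_preseizure: SimulationSpec, spec_seizure: SimulationSpec
) -> tuple[RecordingEpoch, RecordingEpoch]:
    """Paired (pre-seizure, seizure) epochs of equal duration sharing one
    sensor map, mirroring the equal-window-count pairing of clinical events."""
    if abs(spec_preseizure.total_duration_s - spec_seizure.total_duration_s) > 1e-9:
        raise ValidationError(
            "pre-seizure and seizure schedules must have equal total duration "
            f"({spec_preseizure.total_duration_s} s vs {spec_seizure.total_duration_s} s)"
        )
    if spec_preseizure.sensors != spec_seizure.sensors:
        raise ValidationError("paired epochs must share one sensor map")
    pre = simulate_epoch(spec_preseizure, "pre-seizure")
    sz = simulate_epoch(spec_seizure, "seizure")
    return pre, sz


# ---------------------------------------------------------------------------
# canned study-condition generators


def planted_state_specs(
    seed: int,
    n_states: int = 3,
    rows: int = 3,
    cols: int = 4,
    duration_s: float = 48.0,
    block_s: float = 6.0,
    fs: float = 500.0,
    within: float = 0.8,
    between: float = 0.05,
    noise_scale: float = 0.35,
    line_amp: float = 0.3,
) -> SimulationSpec:
    """Spec with ``n_states`` well-separated coupling states interleaved in
    blocks of ``block_s`` seconds — the ground-truth regime used to score
    partition recovery. Block layouts are resampled until every pair of
    states has clearly distinct coupling structure, so the planted states are
    genuinely separable."""
    rng = np.random.default_rng([int(seed), 101])
    sensors = generate_sensor_grid(rows, cols, soz_block=None)
    n = sensors.n_channels
    iu = np.triu_indices(n, k=1)
    coupling: dict = {}
    for k in range(n_states):
        for _ in range(100):
            cand = block_coupling(n, n_blocks=3, within=within, between=between, rng=rng)
            overlap = [
                np.mean((cand[iu] > between) == (prev[iu] > between))
                for prev in coupling.values()
            ]
            if not overlap or max(overlap) < 0.75:
                coupling[k] = cand
                break
        else:  # pragma: no cover - resampling virtually always succeeds
            coupling[k] = cand
    schedule = []
    t = 0.0
    k = 0
    while t < duration_s - 1e-9:
        d = min(block_s, duration_s - t)
        schedule.append((k % n_states, float(round(d))))
        t += d
        k += 1
    return SimulationSpec(
        sensors=sensors,
        state_schedule=schedule,
        coupling_matrices=coupling,
        fs=fs,
        noise_scale=noise_scale,
        line_amp_60hz=line_amp,
        seed=int(seed),
    )


def paper_regime_specs(
    seed: int,
    rows: int = 6,
    cols: int = 6,
    duration_s: float = 60.0,
    fs: float = 512.0,
    soz_boost: float = 2.0,
    distance_decay_mm: float | None = 25.0,
    noise_scale: float = 0.4,
    line_amp: float = 0.4,
) -> tuple[SimulationSpec, SimulationSpec]:
    """Default event regime: a pre-seizure epoch of many short, weak-coupling
    states and a seizure epoch of 3 long states with increasing coupling, a
    boosted SOZ block and distance-decaying coupling on a 6 x 6 grid.

    The SOZ analogue is a persistent hub: within-SOZ base coupling equals the
    active state's within-block coupling in every state, and the
    multiplicative ``soz_boost`` is applied on top. Between-block coupling is
    kept low so the planted structure is spatially local — a large global
    common mode would be removed by the common average reference — and base
    couplings are chosen so the planted gradients sit above the sampling
    floor of max-lag cross-correlation on 1 s windows.
    """
    rng = np.random.default_rng([int(seed), 202])
    sensors = generate_sensor_grid(
        rows, cols, soz_block=((0, 1), (0, 1))
    )
    n = sensors.n_channels
    soz_pair = np.outer(sensors.soz, sensors.soz).astype(bool)
    np.fill_diagonal(soz_pair, False)

    def with_soz_hub(mat: np.ndarray, within: float) -> np.ndarray:
        mat[soz_pair] = np.maximum(mat[soz_pair], within)
        return mat

    pre_coupling = {
        f"ps{k}": with_soz_hub(
            block_coupling(n, 3, within=0.60, between=0.05, rng=rng), 0.60
        )
        for k in range(4)
    }
    n_seg = int(duration_s // 5)
    pre_schedule = [(f"ps{k % 4}", 5.0) for k in range(n_seg)]
    rem = duration_s - 5.0 * n_seg
    if rem > 0:
        pre_schedule.append((f"ps0", float(round(rem))))

    sz_strength = {"s0": 0.70, "s1": 0.80, "s2": 0.90}
    sz_coupling = {
        k: with_soz_hub(block_coupling(n, 2, within=w, between=0.10, rng=rng), w)
        for k, w in sz_strength.items()
    }
    third = round(duration_s / 3.0)
    sz_schedule = [("s0", float(third)), ("s1", float(third)), ("s2", float(duration_s - 2 * third))]

    common = dict(
        sensors=sensors,
        fs=fs,
        soz_boost=soz_boost,
        distance_decay_mm=distance_decay_mm,
        noise_scale=noise_scale,
        line_amp_60hz=line_amp,
        seed=int(seed),
    )
    pre = SimulationSpec(state_schedule=pre_schedule, coupling_matrices=pre_coupling, **common)
    sz = SimulationSpec(state_schedule=sz_schedule, coupling_matrices=sz_coupling, **common)
    return pre, sz
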