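"""Reading and writing recordings, sensor maps and result tables.

Signals travel as plain CSV matrices (samples x channels, header = channel
ids) with a JSON sidecar holding the sampling rate and epoch label, or as EDF
files (read via MNE when installed). Results are long-format CSV tables keyed
by (event, epoch, state) plus a JSON metadata snapshot.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .pipeline import EventResult
from .simulate import RecordingEpoch

__all__ = [
    "write_epoch_csv",
    "read_recording",
    "write_event_result",
    "load_metrics_tables",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epoch_csv(epoch: RecordingEpoch, path) -> Path:
    """Write samples as CSV (rows = samples, columns = channels) plus a JSON
    sidecar with the sampling rate and label."""
    path = Path(path)
    frame = pd.DataFrame(epoch.samples.T, columns=epoch.channel_ids)
    frame.to_csv(path, index=False, float_format="%.10g")
    _sidecar_path(path).write_text(
        json.dumps({"fs": epoch.fs, "label": epoch.label, "n_channels": epoch.n_channels})
    )
    return path


def read_recording(
    path,
    fmt: str | None = None,
    fs: float | None = None,
    label: str | None = None,
) -> RecordingEpoch:
    """Read a recording epoch from CSV (+ JSON sidecar) or EDF.

    For CSV, the sampling rate comes from the sidecar unless ``fs`` is given
    explicitly; the header row carries channel ids in order. EDF reading uses
    MNE (install the ``edf`` extra).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        sidecar = _sidecar_path(path)
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        fs = fs if fs is not None else meta.get("fs")
        label = label if label is not None else meta.get("label")
        if fs is None:
            raise ValidationError(f"sampling rate unknown for {path}: pass fs or provide sidecar")
        if label is None:
            raise ValidationError(f"epoch label unknown for {path}: pass label or provide sidecar")
        frame = pd.read_csv(path)
        samples = frame.to_numpy(dtype=float).T
        if np.isnan(samples).any():
            raise ValidationError(f"{path} contains NaN samples")
        return RecordingEpoch(samples, fs=float(fs), label=label, channel_ids=list(frame.columns))
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - depends on extra
            raise ValidationError("EDF reading requires mne (pip install netstates[edf])") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        samples = raw.get_data()
        if np.isnan(samples).any():
            raise ValidationError(f"{path} contains NaN samples")
        if label is None:
            raise ValidationError("pass label= for EDF files")
        return RecordingEpoch(samples, fs=float(raw.info["sfreq"]), label=label, channel_ids=list(raw.ch_names))
    raise ValidationError(f"unknown recording format: {fmt!r}")


def write_event_result(result: EventResult, outdir) -> Path:
    """Write all result tables and the provenance JSON for one event."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    result.geography.to_csv(outdir / "geography.csv", index=False)
    result.topography.to_csv(outdir / "topography.csv", index=False)
    for epoch, part in result.partitions.items():
        result.state_timeline(epoch).to_csv(
            outdir / f"states_{epoch.replace('-', '_')}.csv", index=False
        )
    meta = {
        "event_id": result.event_id,
        "version": result.version,
        "config": result.config,
        "gammas": result.gammas,
        "flexibility": result.flexibility,
        "thresholds": {
            "strong_cut": result.thresholds.strong_cut,
            "weak_cut": result.thresholds.weak_cut,
            "strong_pct": result.thresholds.strong_pct,
            "weak_pct": result.thresholds.weak_pct,
        },
        "partitions": {
            epoch: {
                "Q": part.Q,
                "gamma": part.gamma,
                "n_optimizations": part.n_optimizations,
                "seed": part.seed,
                "converged": part.converged,
                "retained_states": part.retained_states,
                "preprocessing": part.preprocessing,
            }
            for epoch, part in result.partitions.items()
        },
    }
    (outdir / "result.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_metrics_tables(result_dirs) -> dict[str, pd.DataFrame]:
    """Aggregate per-event CSV tables into cohort-level long tables."""
    tables = {"metrics": [], "geography": [], "topography": []}
    for d in map(Path, result_dirs):
        for name in tables:
            f = d / f"{name}.csv"
            if f.exists():
                frame = pd.read_csv(f)
                if len(frame):
                    tables[name].append(frame)
    return {
        name: (pd.concat(frames, ignore_index=True) if frames else pd.DataFrame())
        for name, frames in tables.items()
    }
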