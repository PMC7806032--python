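"""Reading and writing sensor recordings.

A recording is stored as CSV with header
``time_s,foot_x,foot_y,foot_z,hip_x,hip_y,hip_z,head_x,head_y,head_z``
(SI units: s, m/s²) plus an optional sidecar JSON file (same stem, ``.json``)
holding the trial metadata (label, seed, parameters, rate).  Real multichannel
recordings in the same CSV layout are consumed identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .mechanics import AXES, SITES, SensorRecording

__all__ = ["save_recording", "load_recording", "RECORDING_COLUMNS"]

RECORDING_COLUMNS = ["time_s"] + [f"{site}_{ax}" for site in SITES for ax in AXES]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return None if obj.size > 64 else obj.tolist()  # drop bulky provenance arrays
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_recording(recording: SensorRecording, csv_path: str | Path) -> Path:
    """Write a recording as CSV plus a JSON metadata sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        np.column_stack([recording.t, recording.foot, recording.hip, recording.head]),
        columns=RECORDING_COLUMNS,
    )
    df.to_csv(csv_path, index=False)
    meta = {"rate_hz": recording.rate_hz, **_json_safe(recording.meta)}
    meta.pop("noiseless", None)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def load_recording(csv_path: str | Path, rate_hz: float | None = None) -> SensorRecording:
    """Read a recording CSV (and its JSON sidecar, if present)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"recording CSV lacks columns: {missing}")
    meta = {}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    t = df["time_s"].to_numpy(float)
    if rate_hz is None:
        rate_hz = meta.get("rate_hz")
    if rate_hz is None:
        if len(t) < 2:
            raise InvalidArgumentError("cannot infer sampling rate from one sample")
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    arrays = {
        site: df[[f"{site}_{ax}" for ax in AXES]].to_numpy(float) for site in SITES
    }
    return SensorRecording(rate_hz=float(rate_hz), t=t, meta=meta, **arrays)
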