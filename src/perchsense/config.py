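"""Default configuration for the simulator and the analysis pipeline.

Every tunable number lives here (not hard-coded at call sites) so that a
single JSON file can reproduce a full experiment.  ``load_config`` merges a
user JSON file over :data:`DEFAULTS`; ``default_config`` returns a deep copy
of the defaults.

Units are SI throughout: metres, seconds, kilograms, N/m, N·s/m, m/s².
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any

#: Master defaults.  Mechanics: a two-stage lumped chain — a leg stage
#: (platform to hip mass) and a neck stage (hip to head mass).  The leg stage
#: puts the body resonance at a few Hz; the neck presets are chosen so the
#: head-stage resonance f = (1/2π)√(k_neck/m_head) sits near 2.4 Hz (low) and
#: 3.2 Hz (high), a ≈1.9 stiffness ratio between presets.  Per-axis ±20%
#: asymmetry in k_leg mimics a body that is only symmetric in the sagittal
#: plane.  Axis order is (x lateral, y fore-aft, z vertical).
DEFAULTS: dict[str, Any] = {
    "protocol": {
        "rate_hz": 1000.0,
        "move_duration_s": 0.4,
        "dwell_s": 0.1,
        "n_moves": 3000,
        "max_samples": 50_000_000,
    },
    "mechanics": {
        "m_body": 1.3,
        "m_head": 0.12,
        "k_leg": [1600.0, 2000.0, 2400.0],
        "c_leg": [15.0, 15.0, 15.0],
        "cross_coupling": 0.0,
        "neck_presets": {
            "low": {"k_neck": 26.5, "c_neck": 0.50},
            "high": {"k_neck": 49.3, "c_neck": 0.70},
        },
    },
    "noise": {"sd": 0.05},
    "trials": {"radii_mm": [2, 5, 10, 20], "necks": ["low", "high"]},
    "analysis": {
        "order": 3,
        "s": 10,
        "n_iter": 100,
        "window_s": 40.0,
        "train_samples": 4000,
        "held_out": True,
        "max_lag_s": 0.5,
        "alpha": 0.05,
        "stiffness": {
            "n_iter": 1000,
            "segment_s": 30.0,
            "f_min": 0.5,
            "f_max": 50.0,
            "welch_window_s": 4.0,
        },
    },
    # Scaled-down profile for quick runs: fewer moves per trial and fewer
    # bootstrap iterations; every other setting inherits the defaults.
    "fast_profile": {
        "protocol": {"n_moves": 300},
        "analysis": {"n_iter": 20, "stiffness": {"n_iter": 100}},
    },
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the package defaults."""
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, *, fast: bool = False) -> dict[str, Any]:
    """Load a config, merging a JSON file (if given) over the defaults.

    Parameters
    ----------
    path : str or Path, optional
        JSON file with any subset of the sections in :data:`DEFAULTS`.
    fast : bool
        Apply the scaled-down ``fast_profile`` overrides after merging.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, json.load(fh))
    if fast:
        cfg = _merge(cfg, cfg["fast_profile"])
    return cfg
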