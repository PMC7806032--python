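"""Lumped-parameter compliant-perch simulator.

The perched body is modelled, per axis, as a serial two-stage linear chain:
the platform drives a leg stage (spring k_leg, damper c_leg) carrying the
hip/torso mass, which in turn drives a neck stage (k_neck, c_neck) carrying
the head mass::

    platform --[k_leg, c_leg]-- m_body --[k_neck, c_neck]-- m_head

Feet are rigidly attached to the platform, so foot acceleration is the
platform acceleration itself.  Hip and head accelerometers report the
accelerations of the two masses.  The chain is linear, so it is integrated by
exact zero-order-hold discretization of the continuous state-space at the
sampling rate — bit-reproducible and fast at 1 kHz.

Accelerations are perturbation-induced only (no gravity/DC component): all
downstream analyses operate on fluctuations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .config import default_config
from .exceptions import InvalidArgumentError, UnstableSystemWarning
from .protocol import PerturbationProtocol, generate_protocol

__all__ = [
    "MechanicalParams",
    "SensorRecording",
    "simulate_chain",
    "add_sensor_noise",
    "run_trial",
    "trial_label",
    "parse_trial_label",
    "trial_grid",
]

SITES = ("foot", "hip", "head")
AXES = ("x", "y", "z")


@dataclass
class MechanicalParams:
    """Masses, stiffnesses and dampings of the two-stage chain.

    ``k_leg``/``c_leg`` are per-axis (x lateral, y fore-aft, z vertical);
    ``k_neck``/``c_neck`` are shared across axes.  ``cross_coupling`` adds a
    small symmetric coupling stiffness between the hip coordinates of
    different axes (off by default).
    """

    m_body: float = 1.3
    m_head: float = 0.12
    k_leg: np.ndarray = field(default_factory=lambda: np.array([1600.0, 2000.0, 2400.0]))
    c_leg: np.ndarray = field(default_factory=lambda: np.array([15.0, 15.0, 15.0]))
    k_neck: float = 26.5
    c_neck: float = 0.5
    neck_preset: str = "low"
    cross_coupling: float = 0.0

    def __post_init__(self):
        self.k_leg = np.broadcast_to(np.asarray(self.k_leg, float), (3,)).copy()
        self.c_leg = np.broadcast_to(np.asarray(self.c_leg, float), (3,)).copy()
        if self.m_body <= 0 or self.m_head <= 0:
            raise InvalidArgumentError("masses must be > 0")
        if np.any(self.k_leg <= 0) or self.k_neck <= 0:
            raise InvalidArgumentError("stiffnesses must be > 0")
        if np.any(self.c_leg < 0) or self.c_neck < 0 or self.cross_coupling < 0:
            raise InvalidArgumentError("dampings and coupling must be >= 0")

    @classmethod
    def from_config(cls, mech_cfg: dict | None = None, neck_preset: str = "low") -> "MechanicalParams":
        cfg = mech_cfg if mech_cfg is not None else default_config()["mechanics"]
        presets = cfg["neck_presets"]
        if neck_preset not in presets:
            raise InvalidArgumentError(
                f"unknown neck preset {neck_preset!r}; available: {sorted(presets)}"
            )
        p = presets[neck_preset]
        return cls(
            m_body=cfg["m_body"],
            m_head=cfg["m_head"],
            k_leg=np.asarray(cfg["k_leg"], float),
            c_leg=np.asarray(cfg["c_leg"], float),
            k_neck=p["k_neck"],
            c_neck=p["c_neck"],
            neck_preset=neck_preset,
            cross_coupling=cfg.get("cross_coupling", 0.0),
        )


@dataclass
class SensorRecording:
    """Synchronized 3-axis accelerometer traces at foot, hip and head.

    All traces share one length and one sampling rate; axis order is
    (x lateral, y fore-aft, z vertical), so column 1 is the fore-aft axis.
    ``meta`` records provenance (trial label, neck preset, radius, seeds).
    """

    rate_hz: float
    t: np.ndarray
    foot: np.ndarray
    hip: np.ndarray
    head: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        for site in SITES:
            arr = getattr(self, site)
            if arr.shape != (n, 3):
                raise InvalidArgumentError(
                    f"{site} trace has shape {arr.shape}, expected ({n}, 3)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channels(self, site: str) -> np.ndarray:
        if site not in SITES:
            raise InvalidArgumentError(f"unknown site {site!r}")
        return getattr(self, site)

    def segment(self, start: int, n: int) -> "SensorRecording":
        """Contiguous sub-recording of ``n`` samples starting at ``start``."""
        if start < 0 or start + n > self.n_samples:
            raise InvalidArgumentError("segment out of range")
        sl = slice(start, start + n)
        return replace(
            self,
            t=self.t[sl],
            foot=self.foot[sl],
            hip=self.hip[sl],
            head=self.head[sl],
            meta={**self.meta, "segment_start": start},
        )


def _axis_chain_ss(params: MechanicalParams, axis: int):
    """Continuous state-space of one axis: state [x_h, v_h, x_d, v_d],
    input [p, dp/dt], outputs [hip acc, head acc]."""
    kl, cl = params.k_leg[axis], params.c_leg[axis]
    kn, cn = params.k_neck, params.c_neck
    mb, mh = params.m_body, params.m_head
    A = np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [-(kl + kn) / mb, -(cl + cn) / mb, kn / mb, cn / mb],
            [0.0, 0.0, 0.0, 1.0],
            [kn / mh, cn / mh, -kn / mh, -cn / mh],
        ]
    )
    B = np.array([[0.0, 0.0], [kl / mb, cl / mb], [0.0, 0.0], [0.0, 0.0]])
    C = A[[1, 3], :]
    D = B[[1, 3], :]
    return A, B, C, D


def _coupled_chain_ss(params: MechanicalParams):
    """Full 12-state system with symmetric cross-axis coupling springs
    between the three hip coordinates."""
    n_ax = 3
    A = np.zeros((4 * n_ax, 4 * n_ax))
    B = np.zeros((4 * n_ax, 2 * n_ax))
    for ax in range(n_ax):
        a, b, _, _ = _axis_chain_ss(params, ax)
        A[4 * ax : 4 * ax + 4, 4 * ax : 4 * ax + 4] = a
        B[4 * ax : 4 * ax + 4, 2 * ax : 2 * ax + 2] = b
    kc = params.cross_coupling
    for ax in range(n_ax):
        for other in range(n_ax):
            if other == ax:
                A[4 * ax + 1, 4 * ax] -= 2 * kc / params.m_body
            else:
                A[4 * ax + 1, 4 * other] += kc / params.m_body
    # outputs: hip acc rows then head acc rows, per axis
    C = A[[4 * ax + off for off in (1, 3) for ax in range(n_ax)], :]
    D = B[[4 * ax + off for off in (1, 3) for ax in range(n_ax)], :]
    return A, B, C, D


def _foot_acceleration(platform_pos: np.ndarray, rate_hz: float) -> np.ndarray:
    """Discrete second central difference of platform position × rate²."""
    acc = np.zeros_like(platform_pos)
    if platform_pos.shape[0] >= 3:
        acc[1:-1] = (
            platform_pos[2:] - 2.0 * platform_pos[1:-1] + platform_pos[:-2]
        ) * rate_hz**2
    return acc


def _dsim(Ad, Bd, Cd, Dd, u: np.ndarray) -> np.ndarray:
    """Simulate y(k) = C x(k) + D u(k), x(k+1) = A x(k) + B u(k) from rest."""
    from .subspace import _state_trajectory

    X = _state_trajectory(Ad, Bd, u, np.zeros(Ad.shape[0]))
    return X @ Cd.T + u @ Dd.T


def simulate_chain(protocol: PerturbationProtocol, params: MechanicalParams) -> SensorRecording:
    """Simulate the noiseless chain response to a perturbation protocol.

    Integration is exact zero-order-hold discretization of the per-axis
    linear chain at the protocol's sampling rate.  A non-contractive discrete
    eigenvalue (possible only with zero damping) triggers
    :class:`UnstableSystemWarning` and sets ``meta['unstable']``.
    """
    n = protocol.n_samples
    dt = 1.0 / protocol.rate_hz
    pos, vel = protocol.platform_pos, protocol.platform_vel
    hip = np.zeros((n, 3))
    head = np.zeros((n, 3))
    unstable = False

    if n > 0 and params.cross_coupling > 0:
        A, B, C, D = _coupled_chain_ss(params)
        Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), dt, method="zoh")
        unstable = bool(np.max(np.abs(np.linalg.eigvals(Ad))) >= 1.0 - 1e-12)
        u = np.empty((n, 6))
        u[:, 0::2] = pos
        u[:, 1::2] = vel
        y = _dsim(Ad, Bd, Cd, Dd, u)
        hip = np.ascontiguousarray(y[:, 0:3])
        head = np.ascontiguousarray(y[:, 3:6])
    elif n > 0:
        for ax in range(3):
            A, B, C, D = _axis_chain_ss(params, ax)
            Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), dt, method="zoh")
            if np.max(np.abs(np.linalg.eigvals(Ad))) >= 1.0 - 1e-12:
                unstable = True
            u = np.column_stack([pos[:, ax], vel[:, ax]])
            y = _dsim(Ad, Bd, Cd, Dd, u)
            hip[:, ax] = y[:, 0]
            head[:, ax] = y[:, 1]

    if unstable:
        warnings.warn(
            "discretized chain has a non-contractive eigenvalue; response may not decay",
            UnstableSystemWarning,
        )

    meta = {
        "radius_m": protocol.radius_m,
        "n_moves": protocol.n_moves,
        "neck_preset": params.neck_preset,
        "protocol_seed": protocol.seed,
        "unstable": unstable,
        "noise_sd": 0.0,
    }
    return SensorRecording(
        rate_hz=protocol.rate_hz,
        t=np.arange(n) * dt,
        foot=_foot_acceleration(pos, protocol.rate_hz),
        hip=hip,
        head=head,
        meta=meta,
    )


def add_sensor_noise(
    recording: SensorRecording,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
) -> SensorRecording:
    """Add independent zero-mean Gaussian noise to every channel.

    The noiseless traces are retained under ``meta['noiseless']`` for
    provenance.  ``noise_sd=0`` returns an identical copy.
    """
    if noise_sd < 0:
        raise InvalidArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = {
        **recording.meta,
        "noise_sd": noise_sd,
        "noiseless": {
            "foot": recording.foot.copy(),
            "hip": recording.hip.copy(),
            "head": recording.head.copy(),
        },
    }
    if noise_sd == 0:
        return replace(recording, meta=meta)
    shape = recording.foot.shape
    return replace(
        recording,
        foot=recording.foot + rng.normal(0.0, noise_sd, shape),
        hip=recording.hip + rng.normal(0.0, noise_sd, shape),
        head=recording.head + rng.normal(0.0, noise_sd, shape),
        meta=meta,
    )


_LABEL_RE = re.compile(r"^Trial_(LS|HS)_(\d+)$")
_NECK_CODE = {"low": "LS", "high": "HS"}
_CODE_NECK = {v: k for k, v in _NECK_CODE.items()}


def trial_label(neck_preset: str, radius_m: float) -> str:
    """Build the grid label, e.g. ``Trial_HS_20`` for high neck, 20 mm sphere."""
    if neck_preset not in _NECK_CODE:
        raise InvalidArgumentError(f"unknown neck preset {neck_preset!r}")
    return f"Trial_{_NECK_CODE[neck_preset]}_{round(radius_m * 1000)}"


def parse_trial_label(label: str) -> tuple[str, float]:
    """Parse a grid label into (neck_preset, radius_m)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise InvalidArgumentError(f"trial label {label!r} does not match Trial_(LS|HS)_<mm>")
    return _CODE_NECK[m.group(1)], int(m.group(2)) / 1000.0


def run_trial(
    trial_label_or_none: str | None = None,
    radius_m: float | None = None,
    neck_preset: str | None = None,
    n_moves: int | None = None,
    seed: int = 0,
    config: dict | None = None,
) -> SensorRecording:
    """Simulate one full trial: protocol → chain → sensor noise.

    Either pass a grid label (``Trial_LS_2`` … ``Trial_HS_20``) or explicit
    ``radius_m`` and ``neck_preset``.  The master ``seed`` is split
    deterministically into independent protocol-direction and noise streams,
    so the recording is reproducible from its ``meta`` alone.
    """
    cfg = config if config is not None else default_config()
    if trial_label_or_none is not None:
        neck_preset, radius_m = parse_trial_label(trial_label_or_none)
        label = trial_label_or_none
    else:
        if radius_m is None or neck_preset is None:
            raise InvalidArgumentError("need a trial label or radius_m + neck_preset")
        label = trial_label(neck_preset, radius_m)
    pcfg = cfg["protocol"]
    n_moves = pcfg["n_moves"] if n_moves is None else n_moves

    ss = np.random.SeedSequence(seed)
    proto_ss, noise_ss = ss.spawn(2)
    protocol = generate_protocol(
        n_moves=n_moves,
        radius_m=radius_m,
        move_duration_s=pcfg["move_duration_s"],
        dwell_s=pcfg["dwell_s"],
        rate_hz=pcfg["rate_hz"],
        seed=np.random.default_rng(proto_ss),
        max_samples=pcfg.get("max_samples", 50_000_000),
    )
    params = MechanicalParams.from_config(cfg["mechanics"], neck_preset)
    rec = simulate_chain(protocol, params)
    rec = add_sensor_noise(rec, cfg["noise"]["sd"], seed=np.random.default_rng(noise_ss))
    rec.meta.update(
        trial_label=label,
        seed=seed,
        radius_m=radius_m,
        neck_preset=neck_preset,
        n_moves=n_moves,
        rate_hz=pcfg["rate_hz"],
    )
    return rec


def trial_grid(
    master_seed: int = 0,
    config: dict | None = None,
    n_moves: int | None = None,
) -> dict[str, SensorRecording]:
    """Run the full trial grid (radii × neck presets) with per-trial seeds
    derived deterministically from the master seed."""
    cfg = config if config is not None else default_config()
    grid = {}
    idx = 0
    for neck in cfg["trials"]["necks"]:
        for radius_mm in cfg["trials"]["radii_mm"]:
            seed = int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % (2**31))
            label = trial_label(neck, radius_mm / 1000.0)
            grid[label] = run_trial(label, n_moves=n_moves, seed=seed, config=cfg)
            idx += 1
    return grid
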