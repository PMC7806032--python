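"""Perturbation protocol: random center-out-and-back platform displacements.

The platform executes a series of smooth excursions from the origin to the
surface of a sphere of fixed radius and back, each along a direction drawn
uniformly on the unit sphere — emulating a robot arm commanding random,
uncorrelated point-to-point moves.  The position profile of each excursion is
a half-cosine out and a half-cosine back (zero velocity at both endpoints and
at the peak), followed by a dwell at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CapacityError, InvalidArgumentError

__all__ = ["PerturbationProtocol", "generate_protocol", "random_unit_vectors"]


@dataclass
class PerturbationProtocol:
    """Platform displacement trajectory plus its event list.

    Attributes
    ----------
    rate_hz : float
        Sampling rate of the trajectory (Hz).
    radius_m : float
        Sphere radius of the excursions (m).
    n_moves : int
        Number of center-out-and-back displacements.
    events : list of (int, ndarray)
        Per move, the start sample index and the 3-D unit direction.
    platform_pos : ndarray, shape (N, 3)
        Platform position (m), axis order (x lateral, y fore-aft, z vertical).
    platform_vel : ndarray, shape (N, 3)
        Analytic platform velocity (m/s) of the commanded profile.
    seed : int or None
        Seed used to draw the directions.
    """

    rate_hz: float
    radius_m: float
    n_moves: int
    events: list[tuple[int, np.ndarray]]
    platform_pos: np.ndarray
    platform_vel: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.platform_pos.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` directions uniformly on the unit sphere (Gaussian trick)."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    # Degenerate draws (norm ~ 0) have probability ~0; redraw them anyway.
    while np.any(norms < 1e-12):
        bad = norms < 1e-12
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


def _half_cosine_profile(n_move: int, radius: float, rate_hz: float):
    """Scalar out-and-back profile of length ``n_move`` samples.

    The outbound leg occupies samples 0..n_out and reaches exactly ``radius``
    at sample ``n_out``; the return leg mirrors it.  Returns (pos, vel).
    """
    n_out = n_move // 2
    n_back = n_move - n_out
    k = np.arange(n_move)
    pos = np.empty(n_move)
    vel = np.empty(n_move)
    out = k <= n_out
    pos[out] = radius * 0.5 * (1.0 - np.cos(np.pi * k[out] / n_out))
    vel[out] = radius * 0.5 * (np.pi * rate_hz / n_out) * np.sin(np.pi * k[out] / n_out)
    back = ~out
    kb = n_move - k[back]  # counts n_back-1 .. 1
    pos[back] = radius * 0.5 * (1.0 - np.cos(np.pi * kb / n_back))
    vel[back] = -radius * 0.5 * (np.pi * rate_hz / n_back) * np.sin(np.pi * kb / n_back)
    return pos, vel


def generate_protocol(
    n_moves: int,
    radius_m: float,
    move_duration_s: float = 0.4,
    dwell_s: float = 0.1,
    rate_hz: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    max_samples: int = 50_000_000,
) -> PerturbationProtocol:
    """Generate a random center-out-and-back perturbation protocol.

    Parameters
    ----------
    n_moves : int
        Number of displacements (0 gives an empty, all-zero protocol).
    radius_m : float
        Sphere radius each excursion peaks at (m).
    move_duration_s : float
        Duration of one out-and-back move (s); the peak falls at its midpoint.
    dwell_s : float
        Rest time at the origin after each move (s).
    rate_hz : float
        Sampling rate (Hz).
    seed : int, Generator or None
        Seed for the direction sequence; fixed seed gives a bit-identical
        protocol.
    max_samples : int
        Memory budget; exceeding it raises :class:`CapacityError`.
    """
    if n_moves < 0:
        raise InvalidArgumentError(f"n_moves must be >= 0, got {n_moves}")
    if radius_m <= 0:
        raise InvalidArgumentError(f"radius_m must be > 0, got {radius_m}")
    if move_duration_s <= 0 or dwell_s < 0:
        raise InvalidArgumentError("move_duration_s must be > 0 and dwell_s >= 0")
    if rate_hz <= 0:
        raise InvalidArgumentError(f"rate_hz must be > 0, got {rate_hz}")

    n_move = int(round(move_duration_s * rate_hz))
    n_dwell = int(round(dwell_s * rate_hz))
    if n_move < 2:
        raise InvalidArgumentError("move_duration_s too short for the sampling rate")
    n_block = n_move + n_dwell
    n_total = n_moves * n_block
    if n_total * 3 > max_samples:
        raise CapacityError(
            f"protocol would need {n_total * 3} samples, budget is {max_samples}"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    directions = random_unit_vectors(n_moves, rng)

    pos = np.zeros((n_total, 3))
    vel = np.zeros((n_total, 3))
    prof_pos, prof_vel = _half_cosine_profile(n_move, radius_m, rate_hz) if n_moves else (None, None)
    events: list[tuple[int, np.ndarray]] = []
    for i in range(n_moves):
        start = i * n_block
        d = directions[i]
        pos[start : start + n_move] = prof_pos[:, None] * d[None, :]
        vel[start : start + n_move] = prof_vel[:, None] * d[None, :]
        events.append((start, d))

    return PerturbationProtocol(
        rate_hz=rate_hz,
        radius_m=radius_m,
        n_moves=n_moves,
        events=events,
        platform_pos=pos,
        platform_vel=vel,
        seed=seed if isinstance(seed, int) else None,
        meta={
            "move_duration_s": move_duration_s,
            "dwell_s": dwell_s,
            "n_move_samples": n_move,
            "n_dwell_samples": n_dwell,
        },
    )
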