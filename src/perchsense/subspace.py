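"""MOESP subspace identification of discrete-time state-space models.

The model class maps multichannel sensor acceleration u(k) to foot
acceleration y(k) through::

    x(k+1) = A x(k) + B u(k)
    y(k)   = C x(k) + D u(k)

MOESP (Multivariable Output-Error State-sPace) estimates (A, B, C, D) from
input/output data: block-Hankel matrices of u and y are formed, the output
data are projected onto the orthogonal complement of the input row space,
and the SVD of that projection yields the extended observability matrix —
its column basis gives C and, through shift invariance, A; B, D and the
initial state then follow by ordinary linear least squares.  Fit quality is
scored with the variance-accounted-for (VAF) metric,
100·(1 − var(ŷ−y)/var(y)).

The interface follows the statsmodels convention: construct
:class:`MOESP` from data, call :meth:`~MOESP.fit`, inspect the returned
:class:`StateSpaceResults` (matrices, singular values, ``predict``,
``vaf``, ``summary``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from scipy.signal import fftconvolve

from .exceptions import (
    DegenerateDataError,
    IllConditionedFitError,
    InvalidArgumentError,
    UndefinedVafError,
)
from .mechanics import SensorRecording

__all__ = [
    "MOESP",
    "StateSpaceResults",
    "VafResult",
    "block_hankel",
    "select_order",
    "predict",
    "vaf",
    "markov_parameters",
    "estimate_foot_acc",
]


def block_hankel(data: np.ndarray, s: int) -> np.ndarray:
    """Block-Hankel matrix with ``s`` block rows, channel-major within blocks.

    ``data`` is (N,) or (N, ch); the result is (s·ch) × (N−s+1) with block
    row i holding ``data[i : i+N-s+1].T``.
    """
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if data.ndim != 2:
        raise InvalidArgumentError("data must be 1-D or 2-D (samples × channels)")
    if s < 1:
        raise InvalidArgumentError(f"s must be >= 1, got {s}")
    n, ch = data.shape
    if n < s:
        raise InvalidArgumentError(f"series of length {n} is shorter than s={s}")
    ncols = n - s + 1
    out = np.empty((s * ch, ncols))
    for i in range(s):
        out[i * ch : (i + 1) * ch] = data[i : i + ncols].T
    return out


def select_order(sv: np.ndarray, criterion: str = "gap", max_order: int | None = None) -> int:
    """Model order from a singular-value spectrum.

    ``criterion="gap"`` picks the largest drop in log singular values
    (optionally capped by ``max_order``); ``criterion="fixed:<n>"`` returns
    ``n`` unconditionally.
    """
    sv = np.asarray(sv, float)
    if sv.size == 0:
        raise InvalidArgumentError("sv must be non-empty")
    if criterion.startswith("fixed:"):
        return int(criterion.split(":", 1)[1])
    if sv[0] <= np.finfo(float).tiny or not np.isfinite(sv[0]):
        raise DegenerateDataError("all singular values are below machine tolerance")
    floor = sv[0] * 1e-300
    logs = np.log(np.maximum(sv, floor))
    k = sv.size - 1 if max_order is None else min(max_order, sv.size - 1)
    if k < 1:
        return 1
    gaps = logs[:k] - logs[1 : k + 1]
    return int(np.argmax(gaps)) + 1


def vaf(y_hat: np.ndarray, y: np.ndarray, per_channel: bool = False):
    """Variance accounted for, 100·(1 − var(ŷ−y)/var(y)), in percent.

    Variances are population variances (divide by N).  For multichannel
    data the pooled value is the variance-weighted mean of per-channel VAF,
    i.e. 100·(1 − Σ_c var(e_c)/Σ_c var(y_c)).
    """
    y_hat = np.atleast_2d(np.asarray(y_hat, float).T).T
    y = np.atleast_2d(np.asarray(y, float).T).T
    if y_hat.shape != y.shape:
        raise InvalidArgumentError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    var_y = np.var(y, axis=0)
    if np.any(var_y == 0):
        raise UndefinedVafError("reference signal has a zero-variance channel")
    var_e = np.var(y_hat - y, axis=0)
    per = 100.0 * (1.0 - var_e / var_y)
    if per_channel:
        return per
    return float(100.0 * (1.0 - var_e.sum() / var_y.sum()))


def markov_parameters(A, B, C, D, n_terms: int = 20) -> list[np.ndarray]:
    """Impulse-response coefficients D, CB, CAB, …, CA^(n_terms−2)B."""
    out = [np.atleast_2d(D).astype(float)]
    Ak = np.eye(A.shape[0])
    for _ in range(n_terms - 1):
        out.append(C @ Ak @ B)
        Ak = A @ Ak
    return out


def predict(model, u: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
    """Iterate the state-space recursion over an input series.

    ``model`` is anything with A, B, C, D attributes.  ``u`` is (N, m);
    ``x0`` defaults to zero.  Returns (N, p).
    """
    A, B, C, D = model.A, model.B, model.C, model.D
    u = np.asarray(u, float)
    if u.ndim == 1:
        u = u[:, None]
    n = A.shape[0]
    if u.shape[1] != B.shape[1]:
        raise InvalidArgumentError(
            f"input has {u.shape[1]} channels, model expects {B.shape[1]}"
        )
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, float).ravel()
    N = u.shape[0]
    X = _state_trajectory(A, B, u, x0)
    return X @ C.T + u @ D.T


def _state_trajectory(A: np.ndarray, B: np.ndarray, u: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """States x(k) of x(k+1) = A x(k) + B u(k), vectorized when A is
    diagonalizable (modal decomposition + scalar IIR filters); plain
    recursion otherwise."""
    from scipy.signal import lfilter

    N = u.shape[0]
    n = A.shape[0]
    try:
        lam, V = np.linalg.eig(A)
        if np.linalg.cond(V) > 1e10:
            raise np.linalg.LinAlgError
        W = np.linalg.solve(V, B @ u.T + 0j)  # modal inputs, (n, N)
        z0 = np.linalg.solve(V, x0 + 0j)
        Z = np.empty((n, N), complex)
        k = np.arange(N)
        for i in range(n):
            filt = lfilter([1.0 + 0j], [1.0, -lam[i]], W[i])
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                pow_l = lam[i] ** k if lam[i] != 0 else np.concatenate([[1.0 + 0j], np.zeros(N - 1)])
            Z[i] = pow_l * z0[i]
            Z[i, 1:] += filt[:-1]
        X = np.real(V @ Z).T
        if not np.all(np.isfinite(X)):
            raise np.linalg.LinAlgError
        return X
    except np.linalg.LinAlgError:
        X = np.empty((N, n))
        x = x0.copy()
        for j in range(N):
            X[j] = x
            x = A @ x + B @ u[j]
        return X


@dataclass
class VafResult:
    """VAF of a foot-acceleration estimate from one sensing source."""

    source: str
    per_axis_vaf: np.ndarray
    pooled_vaf: float
    n_train: int


class MOESP:
    """MOESP subspace model of y(k) as a linear dynamic function of u(k).

    Parameters
    ----------
    u : ndarray, shape (N, m) or (N,)
        Input series (e.g. hip and/or head acceleration channels).
    y : ndarray, shape (N, p) or (N,)
        Output series (e.g. foot acceleration channels).
    order : int
        State dimension n of the fitted model.
    s : int
        Number of block rows of the Hankel matrices; must be >= order + 1.
    rate_hz : float, optional
        Sampling rate, stored for reporting only.

    Notes
    -----
    The data length must satisfy N >= 2·s·(m+p), a standard identifiability
    heuristic for the projection step.
    """

    def __init__(
        self,
        u,
        y,
        order: int = 3,
        s: int = 10,
        rate_hz: float | None = None,
        stabilize: bool = True,
    ):
        u = np.asarray(u, float)
        y = np.asarray(y, float)
        if u.ndim == 1:
            u = u[:, None]
        if y.ndim == 1:
            y = y[:, None]
        if u.ndim != 2 or y.ndim != 2 or u.shape[0] != y.shape[0]:
            raise InvalidArgumentError("u and y must be 2-D with equal length")
        if order < 1:
            raise InvalidArgumentError("order must be >= 1")
        if s < order + 1:
            raise InvalidArgumentError(f"s={s} must be >= order+1={order + 1}")
        N, m = u.shape
        p = y.shape[1]
        if N < 2 * s * (m + p):
            raise InvalidArgumentError(
                f"need at least {2 * s * (m + p)} samples for s={s}, m={m}, p={p}; got {N}"
            )
        self.u, self.y = u, y
        self.order, self.s = order, s
        self.rate_hz = rate_hz
        self.stabilize = stabilize
        self.nobs, self.k_inputs, self.k_outputs = N, m, p

    # -- identification steps -------------------------------------------------

    def _project_and_svd(self):
        """Project the output Hankel matrix onto the orthogonal complement of
        the input row space and return its SVD factors."""
        s, m, p = self.s, self.k_inputs, self.k_outputs
        U = block_hankel(self.u, s)
        Y = block_hankel(self.y, s)
        # Orthonormal basis of rowspace(U) via column-pivoted QR of U^T;
        # explicit projection is robust to rank-deficient (duplicated) inputs.
        Q, R, _ = sla.qr(U.T, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        if diag.size and diag[0] > 0:
            rank = int(np.sum(diag > diag[0] * max(U.shape) * np.finfo(float).eps))
        else:
            rank = 0
        Q1 = Q[:, :rank]
        Yperp = Y - (Y @ Q1) @ Q1.T
        Un, sv, _ = np.linalg.svd(Yperp, full_matrices=False)
        return Un, sv

    def fit(self) -> "StateSpaceResults":
        """Identify (A, B, C, D) and the initial state; return results."""
        n, s, m, p, N = self.order, self.s, self.k_inputs, self.k_outputs, self.nobs
        Un, sv = self._project_and_svd()
        if sv[0] <= 0 or not np.isfinite(sv[0]):
            A = np.zeros((n, n))
            C = np.zeros((p, n))
        else:
            # Extended observability estimate, balanced by sqrt of singular values
            gamma = Un[:, :n] * np.sqrt(sv[:n])
            C = gamma[:p].copy()
            G1, G2 = gamma[:-p], gamma[p:]
            A, *_ = np.linalg.lstsq(G1, G2, rcond=None)
        if not np.all(np.isfinite(A)):
            raise IllConditionedFitError(
                "shift-invariance least squares for A produced non-finite values"
            )
        if self.stabilize:
            A = _stabilize(A)
        B, D, x0 = self._solve_bdx0(A, C)
        if not (np.all(np.isfinite(B)) and np.all(np.isfinite(D)) and np.all(np.isfinite(x0))):
            raise IllConditionedFitError(
                "least squares for B, D and the initial state produced non-finite values"
            )
        return StateSpaceResults(self, A, B, C, D, x0, sv)

    def _solve_bdx0(self, A: np.ndarray, C: np.ndarray):
        """B, D and x0 by linear least squares of the simulated response.

        y(k) is linear in (x0, B, D) for fixed (A, C):
        y(k) = C A^k x0 + Σ_τ C A^(k-1-τ) B u(τ) + D u(k).
        """
        n, m, p, N = self.order, self.k_inputs, self.k_outputs, self.nobs
        u, y = self.u, self.y
        # CA[k] = C A^k
        CA = np.empty((N, p, n))
        M = np.eye(n)
        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(N):
                CA[k] = C @ M
                M = A @ M
        if not np.all(np.isfinite(CA)):
            raise IllConditionedFitError(
                "unstable state matrix made the B/D regression diverge "
                "(refit with stabilize=True)"
            )
        # regressor for vec(B): convolution of u_j with g_i(k) = C A^(k-1) e_i
        G = np.zeros((N, p, n))
        G[1:] = CA[:-1]
        conv = fftconvolve(G[:, :, :, None], u[:, None, None, :], axes=0)[:N]
        phi_b = conv.transpose(0, 1, 3, 2).reshape(N, p, m * n)  # col j*n+i
        phi_d = np.zeros((N, p, p * m))
        for j in range(m):
            for a in range(p):
                phi_d[:, a, j * p + a] = u[:, j]
        phi = np.concatenate([CA, phi_b, phi_d], axis=2).reshape(N * p, -1)
        theta, *_ = np.linalg.lstsq(phi, y.ravel(), rcond=None)
        x0 = theta[:n]
        B = theta[n : n + n * m].reshape(m, n).T
        D = theta[n + n * m :].reshape(m, p).T
        return B, D, x0


class StateSpaceResults:
    """Fitted MOESP model: matrices, diagnostics, prediction and scoring."""

    def __init__(self, model: MOESP, A, B, C, D, x0, sv):
        self.model = model
        self.A, self.B, self.C, self.D = A, B, C, D
        self.x0 = x0
        self.sv = np.asarray(sv, float)
        self.order = model.order
        self.k_inputs = model.k_inputs
        self.k_outputs = model.k_outputs
        self.rate_hz = model.rate_hz
        self._fitted: np.ndarray | None = None

    # -- core quantities ------------------------------------------------------

    @property
    def eigenvalues(self) -> np.ndarray:
        """Poles of the fitted model (similarity-invariant)."""
        return np.linalg.eigvals(self.A)

    @property
    def n_params(self) -> int:
        n, m, p = self.order, self.k_inputs, self.k_outputs
        return n * n + n * m + p * n + p * m

    @property
    def fittedvalues(self) -> np.ndarray:
        """In-sample prediction over the training input, from the fitted x0."""
        if self._fitted is None:
            self._fitted = predict(self, self.model.u, self.x0)
        return self._fitted

    def predict(self, u: np.ndarray | None = None, x0: np.ndarray | None = None) -> np.ndarray:
        """Simulate the model over ``u`` (training input by default)."""
        if u is None:
            return self.fittedvalues if x0 is None else predict(self, self.model.u, x0)
        return predict(self, u, x0)

    def markov(self, n_terms: int = 20) -> list[np.ndarray]:
        return markov_parameters(self.A, self.B, self.C, self.D, n_terms)

    def vaf(self, per_channel: bool = False):
        """Identification VAF of the in-sample prediction, in percent."""
        return vaf(self.fittedvalues, self.model.y, per_channel=per_channel)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "MOESP state-space identification results",
            "=" * 44,
            f"order (n):            {self.order}",
            f"inputs (m):           {self.k_inputs}",
            f"outputs (p):          {self.k_outputs}",
            f"samples:              {self.model.nobs}",
            f"block rows (s):       {self.model.s}",
            f"parameters:           {self.n_params}",
        ]
        if self.rate_hz:
            lines.append(f"sampling rate (Hz):   {self.rate_hz:g}")
        ev = ", ".join(f"{v:.4f}" for v in sorted(self.eigenvalues, key=lambda z: -abs(z)))
        lines.append(f"eigenvalues:          {ev}")
        sv_head = ", ".join(f"{v:.3e}" for v in self.sv[: 2 * self.order])
        lines.append(f"singular values:      {sv_head}")
        per = self.vaf(per_channel=True)
        lines.append("VAF per channel (%):  " + ", ".join(f"{v:.2f}" for v in per))
        lines.append(f"VAF pooled (%):       {self.vaf():.2f}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "x0": np.asarray(self.x0).tolist(),
            "sv": self.sv.tolist(),
            "order": self.order,
            "k_inputs": self.k_inputs,
            "k_outputs": self.k_outputs,
            "rate_hz": self.rate_hz,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load_matrices(path: str | Path) -> dict:
        """Load a saved model as a dict of arrays (A, B, C, D, x0, sv, …)."""
        payload = json.loads(Path(path).read_text())
        for key in ("A", "B", "C", "D", "x0", "sv"):
            payload[key] = np.asarray(payload[key], float)
        return payload


def _stabilize(A: np.ndarray, max_radius: float = 1.0 - 1e-6) -> np.ndarray:
    """Project an estimated state matrix onto the stable set.

    Eigenvalues with |λ| >= 1 are reflected inside the unit circle
    (λ → λ/|λ|², capped at ``max_radius``), keeping their phase, so
    marginal oscillatory modes picked up from quasi-periodic excitation
    become slowly decaying instead of divergent.  A stable estimate passes
    through untouched, so exact-recovery behaviour on stable systems is
    unaffected.  Falls back to uniform shrinkage if A is defective.
    """
    lam, V = np.linalg.eig(A)
    mags = np.abs(lam)
    if np.all(mags < 1.0):
        return A
    lam = np.where(mags >= 1.0, lam * np.minimum(1.0 / mags**2, max_radius / mags), lam)
    with np.errstate(all="ignore"):
        try:
            A_stab = np.real(V @ np.diag(lam) @ np.linalg.inv(V))
        except np.linalg.LinAlgError:
            A_stab = A * (max_radius / mags.max())
    if not np.all(np.isfinite(A_stab)) or np.max(np.abs(np.linalg.eigvals(A_stab))) >= 1.0:
        A_stab = A * (max_radius / mags.max())
    return A_stab


_SOURCES = ("hip", "head", "fusion")


def estimate_foot_acc(
    recording: SensorRecording,
    source: str,
    order: int = 3,
    s: int = 10,
    window: tuple[float, float] | None = None,
    train_samples: int | None = None,
    held_out: bool = False,
    clip_negative: bool = False,
) -> VafResult:
    """Fit a MOESP model predicting foot acceleration from one sensing source.

    ``source`` is "hip" or "head" (3 input channels) or "fusion" (hip and
    head stacked, 6 channels); the output is always the 3-axis foot
    acceleration.  ``window`` is a (start_s, stop_s) span of the recording;
    ``train_samples`` restricts the fit to the first that many samples of
    the window.  By default the identification VAF is scored in-sample on
    the training span; with ``held_out`` the model is scored on the rest of
    the window instead (zero initial state).
    """
    if source not in _SOURCES:
        raise InvalidArgumentError(f"source must be one of {_SOURCES}, got {source!r}")
    if window is not None:
        i0 = int(round(window[0] * recording.rate_hz))
        i1 = int(round(window[1] * recording.rate_hz))
        if not (0 <= i0 < i1 <= recording.n_samples):
            raise InvalidArgumentError("window outside the recording")
        recording = recording.segment(i0, i1 - i0)
    if source == "fusion":
        u = np.hstack([recording.hip, recording.head])
    else:
        u = recording.channels(source)
    y = recording.foot
    n_train = u.shape[0] if train_samples is None else min(train_samples, u.shape[0])
    res = MOESP(u[:n_train], y[:n_train], order=order, s=s, rate_hz=recording.rate_hz).fit()
    if held_out and n_train < u.shape[0]:
        y_hat, y_ref = res.predict(u[n_train:]), y[n_train:]
    else:
        y_hat, y_ref = res.fittedvalues, y[:n_train]
    per = vaf(y_hat, y_ref, per_channel=True)
    pooled = vaf(y_hat, y_ref)
    if clip_negative:
        per = np.maximum(per, 0.0)
        pooled = max(pooled, 0.0)
    return VafResult(source=source, per_axis_vaf=per, pooled_vaf=pooled, n_train=n_train)
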