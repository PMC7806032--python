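"""Mechanics estimators: resonance-based stiffness and cross-correlation delays.

Effective stiffness is inferred from the resonant frequency of head
acceleration via the lumped relation K = m f² (f in Hz).  Note this estimator
is *proportional*, not equal, to the physical spring constant: the harmonic
oscillator gives k = m (2πf)², so K = k/(2π)².  The proportionality is
harmless for comparisons between conditions, which is how it is used.

Propagation delays between sensor sites are the lag at the maximum of the
normalized cross-correlation between the foot trace and the hip or head
trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import (
    InvalidArgumentError,
    NoDominantResonanceWarning,
    UndefinedCorrelationError,
)
from .mechanics import AXES, SensorRecording

__all__ = [
    "StiffnessEstimate",
    "DelayEstimate",
    "resonant_frequency",
    "stiffness_eq1",
    "xcorr_delay",
    "stiffness_bootstrap",
    "delay_estimates",
]


@dataclass
class StiffnessEstimate:
    """Stiffness K = m f² from a resonant-frequency measurement."""

    f_hz: float
    m_kg: float
    K: float
    segment_s: float

    def __post_init__(self):
        if self.f_hz < 0:
            raise InvalidArgumentError("f_hz must be >= 0")
        assert abs(self.K - self.m_kg * self.f_hz**2) < 1e-9 * max(1.0, self.K)


@dataclass
class DelayEstimate:
    """Lag of the cross-correlation maximum between two sensor traces.

    ``delay_s`` > 0 means the second signal lags the reference; ``axis`` is
    an axis label or "pooled".
    """

    pair: str
    axis: str
    delay_s: float
    peak_corr: float


def resonant_frequency(
    trace: np.ndarray,
    rate_hz: float,
    f_min: float = 0.5,
    f_max: float = 50.0,
    window_s: float = 4.0,
    full_output: bool = False,
):
    """Frequency of maximal Welch power within [f_min, f_max].

    The trace is mean-removed; the spectrum uses Hann windows of
    ``window_s`` seconds with 50% overlap.  If the peak is not prominent
    (less than 10× the median in-band power) a
    :class:`NoDominantResonanceWarning` is emitted and, with
    ``full_output``, flagged in the diagnostics dict.
    """
    trace = np.asarray(trace, float)
    if trace.ndim != 1:
        raise InvalidArgumentError("trace must be 1-D")
    if rate_hz <= 0:
        raise InvalidArgumentError("rate_hz must be > 0")
    if not (0 <= f_min < f_max <= rate_hz / 2):
        raise InvalidArgumentError("need 0 <= f_min < f_max <= Nyquist")
    nperseg = int(round(window_s * rate_hz))
    if trace.size < nperseg:
        raise InvalidArgumentError(
            f"trace of {trace.size} samples is shorter than one spectral window ({nperseg})"
        )
    freqs, psd = signal.welch(
        trace - trace.mean(),
        fs=rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    band = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(band):
        raise InvalidArgumentError("no spectral bins inside [f_min, f_max]")
    fb, pb = freqs[band], psd[band]
    i = int(np.argmax(pb))
    prominent = bool(pb[i] > 10.0 * np.median(pb)) if pb.size > 1 else True
    if not prominent:
        warnings.warn(
            "spectral peak is not prominent: no dominant resonance",
            NoDominantResonanceWarning,
        )
    f_hz = float(fb[i])
    if full_output:
        return f_hz, {
            "freqs": fb,
            "psd": pb,
            "peak_power": float(pb[i]),
            "prominent": prominent,
        }
    return f_hz


def stiffness_eq1(m_kg: float, f_hz: float) -> float:
    """Effective stiffness K = m f² (N/m) from mass and resonant frequency."""
    if m_kg <= 0:
        raise InvalidArgumentError(f"mass must be > 0, got {m_kg}")
    if f_hz < 0:
        raise InvalidArgumentError(f"f_hz must be >= 0, got {f_hz}")
    return m_kg * f_hz**2


def xcorr_delay(
    ref: np.ndarray,
    sig: np.ndarray,
    rate_hz: float,
    max_lag_s: float = 0.5,
    pair: str = "",
    axis: str = "",
) -> DelayEstimate:
    """Delay of ``sig`` relative to ``ref`` from the cross-correlation peak.

    Both series are mean-removed; the normalized cross-correlation is scanned
    over lags in [−max_lag_s, +max_lag_s].  Positive delay means ``sig`` lags
    ``ref``.  Exact ties are broken toward the smallest |lag|, then negative
    before positive.
    """
    ref = np.asarray(ref, float)
    sig = np.asarray(sig, float)
    if ref.shape != sig.shape or ref.ndim != 1:
        raise InvalidArgumentError("ref and sig must be equal-length 1-D series")
    n = ref.size
    if rate_hz <= 0:
        raise InvalidArgumentError("rate_hz must be > 0")
    max_lag = int(round(max_lag_s * rate_hz))
    if max_lag >= n:
        raise InvalidArgumentError("max_lag_s must be shorter than the trace")
    ref = ref - ref.mean()
    sig = sig - sig.mean()
    sd_r = np.sqrt(np.mean(ref**2))
    sd_s = np.sqrt(np.mean(sig**2))
    if sd_r == 0 or sd_s == 0:
        raise UndefinedCorrelationError("zero-variance input: correlation undefined")
    # correlate(sig, ref)[lag l] = sum_k sig[k] ref[k-l]: peaks at l=d when
    # sig is ref delayed by d samples
    c = signal.correlate(sig, ref, mode="full", method="auto")
    lags = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    c, lags = c[keep] / (n * sd_r * sd_s), lags[keep]
    peak = np.max(c)
    ties = np.flatnonzero(c == peak)
    # smallest |lag| first; among ±d, negative first
    best = min(ties, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    return DelayEstimate(
        pair=pair,
        axis=axis,
        delay_s=float(lags[best] / rate_hz),
        peak_corr=float(np.clip(c[best], -1.0, 1.0)),
    )


def delay_estimates(
    recording: SensorRecording,
    site: str,
    max_lag_s: float = 0.5,
) -> list[DelayEstimate]:
    """Per-axis foot→site delays for one recording (site: 'hip' or 'head')."""
    out = []
    for ax in range(3):
        out.append(
            xcorr_delay(
                recording.foot[:, ax],
                recording.channels(site)[:, ax],
                recording.rate_hz,
                max_lag_s=max_lag_s,
                pair=f"foot->{site}",
                axis=AXES[ax],
            )
        )
    return out


def stiffness_bootstrap(
    recording: SensorRecording,
    m_kg: float,
    n_iter: int = 1000,
    segment_s: float = 30.0,
    seed: int | np.random.Generator | None = None,
    f_min: float = 0.5,
    f_max: float = 50.0,
    welch_window_s: float = 4.0,
):
    """Bootstrap the stiffness estimate over random head-channel segments.

    Each iteration draws (with replacement) a contiguous ``segment_s`` window
    and a random axis of the head trace, measures the resonant frequency and
    converts it to K = m f².  Drawing the axis at random propagates the
    direction dependence of the chain's response into the bootstrap spread.
    Returns a :class:`~perchsense.resampling.BootstrapResult`.
    """
    from .resampling import BootstrapResult  # local import to avoid a cycle

    if recording.duration_s < segment_s:
        raise InvalidArgumentError("recording shorter than segment_s")
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_seg = int(round(segment_s * recording.rate_hz))
    starts = rng.integers(0, recording.n_samples - n_seg + 1, size=n_iter)
    axes = rng.integers(0, 3, size=n_iter)
    values = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoDominantResonanceWarning)
        for start, ax in zip(starts, axes):
            try:
                f = resonant_frequency(
                    recording.head[start : start + n_seg, ax],
                    recording.rate_hz,
                    f_min=f_min,
                    f_max=f_max,
                    window_s=welch_window_s,
                )
                values.append(stiffness_eq1(m_kg, f))
            except (InvalidArgumentError, UndefinedCorrelationError):
                n_failed += 1
    return BootstrapResult.from_values(
        statistic_name="stiffness_N_per_m",
        values=np.asarray(values),
        n_iter=n_iter,
        window_s=segment_s,
        n_failed=n_failed,
        seed=seed if isinstance(seed, int) else None,
    )
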