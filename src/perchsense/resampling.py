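"""Bootstrap resampling over recording windows and pairwise comparisons.

Statistics are re-estimated on randomly positioned contiguous windows drawn
with replacement from a recording; central tendency is reported as the
median with interquartile range.  Because windows overlap, per-iteration
values are not independent and t-tests computed from them are
anti-conservative; :class:`~perchsense.exceptions.OverlappingWindowsWarning`
is emitted whenever overlap is certain.  The procedure is kept as-is for
fidelity with common practice in rig studies; treat p-values as descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .exceptions import InvalidArgumentError, OverlappingWindowsWarning, PerchsenseError
from .mechanics import SensorRecording

__all__ = ["BootstrapResult", "ComparisonResult", "bootstrap_windows", "summarize", "compare"]


def summarize(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q25, q75) with linear-interpolation (type-7) quantiles."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise InvalidArgumentError("cannot summarize an empty sample")
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q25), float(q75)


@dataclass
class BootstrapResult:
    """Per-iteration statistic values plus median/IQR summary."""

    statistic_name: str
    values: np.ndarray
    n_iter: int
    window_s: float
    median: float
    q25: float
    q75: float
    n_failed: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_values(
        cls,
        statistic_name: str,
        values: np.ndarray,
        n_iter: int,
        window_s: float,
        n_failed: int = 0,
        seed: int | None = None,
        meta: dict | None = None,
    ) -> "BootstrapResult":
        values = np.asarray(values, float).ravel()
        med, q25, q75 = summarize(values)
        return cls(
            statistic_name=statistic_name,
            values=values,
            n_iter=n_iter,
            window_s=window_s,
            median=med,
            q25=q25,
            q75=q75,
            n_failed=n_failed,
            seed=seed,
            meta=meta or {},
        )

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


@dataclass
class ComparisonResult:
    """Two-sample t-test between condition-level bootstrap values."""

    pair: tuple[str, str]
    t_stat: float
    p_value: float
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    significant: bool
    alpha: float = 0.05
    degenerate: bool = False


def bootstrap_windows(
    recording: SensorRecording,
    stat_fn: Callable[[SensorRecording], float | np.ndarray],
    n_iter: int = 100,
    window_s: float = 40.0,
    seed: int | np.random.Generator | None = None,
    statistic_name: str = "statistic",
) -> BootstrapResult:
    """Apply ``stat_fn`` to ``n_iter`` random contiguous windows.

    Window starts are uniform over the admissible range, drawn with
    replacement (windows may overlap).  ``stat_fn`` receives a
    :class:`SensorRecording` slice and may return a scalar or an array
    (arrays are flattened into the pooled value list, e.g. per-axis delays).
    Failing iterations are dropped and counted in ``n_failed``; the call
    fails only if every iteration fails.
    """
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    n_win = int(round(window_s * recording.rate_hz))
    if n_win > recording.n_samples:
        raise InvalidArgumentError(
            f"window_s={window_s} exceeds recording duration {recording.duration_s:.1f} s"
        )
    if n_iter * window_s > recording.duration_s:
        warnings.warn(
            "bootstrap windows necessarily overlap; t-tests on these values "
            "are anti-conservative",
            OverlappingWindowsWarning,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(0, recording.n_samples - n_win + 1, size=n_iter)
    values: list[np.ndarray] = []
    n_failed = 0
    for start in starts:
        try:
            v = stat_fn(recording.segment(int(start), n_win))
            values.append(np.atleast_1d(np.asarray(v, float)).ravel())
        except PerchsenseError:
            n_failed += 1
    if not values:
        raise PerchsenseError("all bootstrap iterations failed")
    return BootstrapResult.from_values(
        statistic_name=statistic_name,
        values=np.concatenate(values),
        n_iter=n_iter,
        window_s=window_s,
        n_failed=n_failed,
        seed=seed if isinstance(seed, int) else None,
    )


def compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sample t-test (Welch by default) between two value sets.

    Both sides need at least 2 values.  If both sides have zero variance and
    equal means the comparison is degenerate: p = 1 by convention, flagged.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each side needs at least 2 values")
    med_a, q25_a, q75_a = summarize(a)
    med_b, q25_b, q75_b = summarize(b)
    degenerate = False
    if np.var(a) == 0 and np.var(b) == 0:
        degenerate = True
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    return ComparisonResult(
        pair=labels,
        t_stat=t_stat,
        p_value=p,
        median_a=med_a,
        iqr_a=q75_a - q25_a,
        median_b=med_b,
        iqr_b=q75_b - q25_b,
        significant=bool(p < alpha),
        alpha=alpha,
        degenerate=degenerate,
    )
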