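"""Screening-performance statistics.

Given a complete screening trace (the order in which a reviewer decided all
N references) and the ground-truth relevance labels, this module computes:

* the cumulative recall curve recall(i) = TP(i) / R,
* **WSS@95%** = 0.95 − i_R95 / N, the fraction of the collection spared by
  stopping at i_R95 = min{ i : recall(i) ≥ 0.95 }, relative to screening in
  random order,
* the **exact null distribution** of i_R95 under a uniformly random
  ordering.  With r = ⌈0.95·R⌉ inclusions required,

      P(i_R95 = i) = C(N−R, i−r)·C(R, r−1) / C(N, i−1) · (R−r+1)/(N−i+1)

  on the support r ≤ i ≤ N−(R−r): a hypergeometric draw of r−1 inclusions
  among the first i−1 references times the chance that the r-th inclusion
  lands exactly at position i.  The p-value is the lower tail
  Σ_{i≤i_R95} P(i_R95 = i),
* **AUR** = Σ_i recall(i) / (N − (R−1)/2), the normalised area under the
  recall curve — exactly 1 for perfect prioritisation (all relevant first),
  ≈ (N+1)/2 / (N − (R−1)/2) ≈ 0.5 under random ordering,
* **running recall** against a baseline decision set in a moving window of
  relevant references (complacency diagnostic), and
* sliding-window **median decision times**.

Binomials are evaluated in log-space (gammaln), so collections of several
thousand references pose no overflow problem.  The 95% threshold is applied
as the integer ceiling ⌈19R/20⌉ to avoid floating-point boundary errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, FormatError, UndefinedMetricError

__all__ = [
    "ScreeningTrace",
    "RecallCurve",
    "Wss95Result",
    "AurResult",
    "recall_curve",
    "wss95",
    "exact_null_pmf",
    "exact_null_support",
    "exact_pvalue",
    "aur",
    "running_recall",
    "smooth_decision_times",
    "r_needed",
    "plot_recall_curve",
]


@dataclass(frozen=True)
class ScreeningTrace:
    """An ordered, labelled screening process.

    ``records``: (reference id, decision, optional ISO timestamp) in
    screening order.  ``ground_truth``: id -> True (relevant) / False.
    """

    records: tuple[tuple[str, str, str | None], ...]
    ground_truth: dict[str, bool]

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("trace contains duplicate reference ids")

    @classmethod
    def from_rows(
        cls, rows: list[tuple[str, str, str | None]], ground_truth: dict[str, bool]
    ) -> "ScreeningTrace":
        return cls(records=tuple(rows), ground_truth=dict(ground_truth))

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def is_complete(self) -> bool:
        return set(self.ids) == set(self.ground_truth)


@dataclass(frozen=True)
class RecallCurve:
    N: int
    R: int
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    recall: np.ndarray


@dataclass(frozen=True)
class Wss95Result:
    wss95: float
    i_r95: int
    r_needed: int
    p_value: float


@dataclass(frozen=True)
class AurResult:
    aur: float
    normaliser: float


def r_needed(R: int) -> int:
    """⌈0.95·R⌉ computed over integers as ⌈19R/20⌉."""
    return -((-19 * R) // 20)


def recall_curve(trace: ScreeningTrace) -> RecallCurve:
    """Cumulative TP/FP/FN/recall per screening position (complete traces)."""
    missing = [i for i in trace.ids if i not in trace.ground_truth]
    if missing:
        raise FormatError(f"no ground truth for ids: {missing[:5]}")
    if not trace.is_complete():
        raise UndefinedMetricError(
            "recall requires a complete trace covering every reference"
        )
    rel = np.array([trace.ground_truth[i] for i in trace.ids], dtype=np.int64)
    R = int(rel.sum())
    if R == 0:
        raise UndefinedMetricError("no relevant references: recall is undefined")
    tp = np.cumsum(rel)
    positions = np.arange(1, len(rel) + 1)
    return RecallCurve(
        N=len(rel), R=R, tp=tp, fp=positions - tp, fn=R - tp, recall=tp / R
    )


def wss95(curve: RecallCurve) -> Wss95Result:
    """Work saved over sampling at 95% recall, with its exact p-value."""
    r = r_needed(curve.R)
    hit = np.nonzero(curve.tp >= r)[0]
    i_r95 = int(hit[0]) + 1  # positions are 1-based
    return Wss95Result(
        wss95=0.95 - i_r95 / curve.N,
        i_r95=i_r95,
        r_needed=r,
        p_value=exact_pvalue(curve.N, curve.R, i_r95),
    )


def _log_choose(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def exact_null_support(N: int, R: int) -> tuple[int, int]:
    r = r_needed(R)
    return r, N - (R - r)


def exact_null_pmf(N: int, R: int, i) -> np.ndarray | float:
    """P(i_R95 = i) under a uniformly random ordering (0 outside support)."""
    if R < 1 or R > N:
        raise UndefinedMetricError(f"invalid R={R} for N={N}")
    r = r_needed(R)
    i_arr = np.atleast_1d(np.asarray(i, dtype=np.int64))
    lo, hi = exact_null_support(N, R)
    valid = (i_arr >= lo) & (i_arr <= hi)
    out = np.zeros(i_arr.shape, dtype=np.float64)
    if valid.any():
        iv = i_arr[valid]
        log_p = (
            _log_choose(N - R, iv - r)
            + _log_choose(R, r - 1)
            - _log_choose(N, iv - 1)
            + np.log(R - r + 1)
            - np.log(N - iv + 1)
        )
        out[valid] = np.exp(log_p)
    return out if np.ndim(i) else float(out[0])


def exact_pvalue(N: int, R: int, i_r95: int) -> float:
    """P(i_R95 ≤ observed) under the random-ordering null, clipped to (0, 1]."""
    lo, hi = exact_null_support(N, R)
    if i_r95 < lo:
        raise UndefinedMetricError(f"i_R95={i_r95} below the support minimum {lo}")
    upper = min(i_r95, hi)
    p = float(np.sum(exact_null_pmf(N, R, np.arange(lo, upper + 1))))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def aur(curve: RecallCurve) -> AurResult:
    """Normalised area under the recall curve (1 = perfect prioritisation)."""
    if curve.R < 1:
        raise UndefinedMetricError("AUR undefined for R=0")
    normaliser = curve.N - (curve.R - 1) / 2
    return AurResult(aur=float(curve.recall.sum() / normaliser), normaliser=normaliser)


def running_recall(
    trace: ScreeningTrace, baseline: set[str], window: int = 50
) -> pd.Series:
    """Windowed agreement with a baseline decision set.

    Each time the trace consumes a baseline-relevant reference, record
    whether the screener marked it *include*; the series holds, at each
    trace position where at least ``window`` baseline-relevant references
    have been consumed, the fraction of the last ``window`` of them marked
    include.  Indexed by 1-based trace position.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    marks: list[int] = []
    positions: list[int] = []
    values: list[float] = []
    for pos, (ref_id, decision, _) in enumerate(trace.records, start=1):
        if ref_id in baseline:
            marks.append(1 if decision == "include" else 0)
            if len(marks) >= window:
                positions.append(pos)
                values.append(float(np.mean(marks[-window:])))
    if not values:
        warnings.warn(
            f"fewer than window={window} baseline-relevant references; "
            "returning a single global value",
            stacklevel=2,
        )
        if not marks:
            raise UndefinedMetricError("trace contains no baseline-relevant references")
        return pd.Series([float(np.mean(marks))], index=[len(trace.records)],
                         name="running_recall")
    return pd.Series(values, index=positions, name="running_recall")


def smooth_decision_times(timestamps, window: int = 51) -> pd.Series:
    """Centred sliding-window medians of interdecision intervals.

    ``timestamps`` may be numeric seconds or anything pandas parses as
    datetimes; they must be strictly increasing and ``window`` odd.  Edge
    windows are truncated.
    """
    if window % 2 != 1 or window < 1:
        raise ConfigurationError("window must be odd and positive")
    ts = pd.Series(timestamps)
    if not pd.api.types.is_numeric_dtype(ts):
        ts = pd.to_datetime(ts).astype("int64") / 1e9
    intervals = ts.diff().dropna()
    if (intervals <= 0).any():
        raise FormatError("timestamps must be strictly increasing")
    smoothed = intervals.rolling(window, center=True, min_periods=1).median()
    smoothed.index = range(1, len(smoothed) + 1)
    return smoothed.rename("median_interval_s")


def plot_recall_curve(curve: RecallCurve, ax=None, label: str | None = None):
    """Plot recall(i) against the random-ordering diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(1, curve.N + 1)
    ax.plot(x, curve.recall, label=label or "screening order")
    ax.plot(x, x / curve.N, linestyle="--", color="grey", label="random expectation")
    ax.set_xlabel("references screened")
    ax.set_ylabel("recall")
    ax.legend()
    return ax
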