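"""Changepoint detection for monthly count series.

Implements PELT (Pruned Exact Linear Time) with a Gaussian
mean-and-variance segment cost: a segmentation is scored by

    sum_segments  -2 * max log N(x_seg | mu_seg, sigma_seg^2)  +  beta * (#changepoints)

and PELT returns the exact optimum while pruning candidate change
locations.  An O(n^2) optimal-partitioning dynamic program with no
pruning is provided as an independent oracle; on any input both must
return identical segmentations and total cost.

Named penalties: ``"BIC"`` is ``(p + 1) * log n`` with ``p = 2``
distribution parameters per extra segment (the +1 counts the changepoint
location); ``"MBIC"`` uses ``(p + 2) * log n`` and adds ``log(seg
length)`` to each segment's cost (the modified BIC of the changepoint
literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

try:  # sklearn is optional at import time; the estimator API works without it
    from sklearn.base import BaseEstimator
except Exception:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

from .io_formats import MonthlySeries

_LOG_2PI = float(np.log(2.0 * np.pi))

#: distribution parameters per segment for the mean+variance Gaussian cost
_P_MEANVAR = 2


@dataclass
class ChangepointResult:
    """Segmentation of a series.

    ``breakpoints`` are 1-based end positions of the segments (the last
    element is always the series length), so a single interior
    changepoint at month 32 of a 48-month series is ``[32, 48]``.
    """

    breakpoints: list[int]
    segments: pd.DataFrame
    penalty: float
    penalty_name: str
    cost_name: str
    total_cost: float
    start: pd.Period | None = None
    country: str | None = None

    @property
    def n_changepoints(self) -> int:
        return len(self.breakpoints) - 1

    @property
    def changepoint_months(self) -> list[str]:
        """Calendar months of the first month of each new segment."""
        if self.start is None:
            return []
        return [str(self.start + b) for b in self.breakpoints[:-1]]

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "breakpoints": list(map(int, self.breakpoints)),
            "changepoint_months": self.changepoint_months,
            "segments": self.segments.to_dict(orient="records"),
            "penalty": float(self.penalty),
            "penalty_name": self.penalty_name,
            "cost_name": self.cost_name,
            "total_cost": float(self.total_cost),
        }


def moving_mean(x: Sequence[float] | MonthlySeries, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows.

    At position ``i`` the mean is taken over the available points in
    ``[i - h, i + h]`` with ``h = (window - 1) / 2``, so the output has
    the same length as the input.
    """
    if isinstance(x, MonthlySeries):
        x = x.counts
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    h = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = x[lo:hi].mean()
    return out


class _MeanVarCost:
    """Per-segment costs from prefix sums; O(1) per query.

    The segment cost is twice the negative Gaussian log-likelihood
    maximized under the constraint ``sigma^2 >= var_floor``; the
    constrained form (rather than clamping the variance inside the
    unconstrained formula) keeps the cost subadditive, which PELT's
    pruning requires.
    """

    name = "meanvar_normal"

    def __init__(self, x: np.ndarray, var_floor: float = 0.25, seglen_term: bool = False):
        x = np.asarray(x, dtype=float)
        self.n = len(x)
        self.s1 = np.concatenate([[0.0], np.cumsum(x)])
        self.s2 = np.concatenate([[0.0], np.cumsum(x * x)])
        self.var_floor = float(var_floor)
        self.seglen_term = seglen_term
        self.floored = False

    def cost(self, s: int, e: int) -> float:
        """Cost of segment covering x[s:e] (half-open), e > s."""
        n = e - s
        sm = self.s1[e] - self.s1[s]
        sq = self.s2[e] - self.s2[s]
        var = sq / n - (sm / n) ** 2
        if var < self.var_floor:
            self.floored = True
            c = n * (_LOG_2PI + np.log(self.var_floor)) + n * var / self.var_floor
        else:
            c = n * (_LOG_2PI + np.log(var) + 1.0)
        if self.seglen_term:
            c += np.log(n)
        return c


class _PoissonCost:
    """Twice the negative maximized Poisson log-likelihood (constants dropped)."""

    name = "poisson"

    def __init__(self, x: np.ndarray, var_floor: float = 0.25, seglen_term: bool = False):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("Poisson cost requires non-negative counts")
        self.n = len(x)
        self.s1 = np.concatenate([[0.0], np.cumsum(x)])
        self.seglen_term = seglen_term

    def cost(self, s: int, e: int) -> float:
        n = e - s
        sm = self.s1[e] - self.s1[s]
        c = 2.0 * (sm - sm * np.log(sm / n)) if sm > 0 else 0.0
        if self.seglen_term:
            c += np.log(n)
        return c

_COSTS = {"meanvar_normal": _MeanVarCost, "poisson": _PoissonCost}


def _resolve_penalty(penalty: float | str, n: int) -> tuple[float, str, bool]:
    """Return (penalty value, name, whether cost carries a log-seglen term)."""
    if isinstance(penalty, str):
        name = penalty.upper()
        if name == "BIC":
            return (_P_MEANVAR + 1) * np.log(n), "BIC", False
        if name == "MBIC":
            return (_P_MEANVAR + 2) * np.log(n), "MBIC", True
        raise ValueError(f"unknown penalty {penalty!r}")
    value = float(penalty)
    if value < 0:
        raise ValueError("penalty must be non-negative")
    return value, "manual", False


def _segment_table(
    x: np.ndarray, breakpoints: Sequence[int], start: pd.Period | None
) -> pd.DataFrame:
    rows = []
    prev = 0
    for b in breakpoints:
        seg = x[prev:b]
        rows.append(
            {
                "start": prev + 1,
                "end": int(b),
                "start_month": str(start + prev) if start is not None else None,
                "end_month": str(start + b - 1) if start is not None else None,
                "n": len(seg),
                "mean": float(np.mean(seg)),
                "sd": float(np.std(seg, ddof=1)) if len(seg) > 1 else float("nan"),
            }
        )
        prev = b
    return pd.DataFrame(rows)


class PeltMeanVar(BaseEstimator):
    """PELT changepoint detector with a Gaussian mean+variance cost.

    Parameters
    ----------
    penalty:
        Non-negative float, or ``"BIC"`` / ``"MBIC"`` (default; the
        modified BIC commonly used for this cost).
    minseglen:
        Minimum segment length, default 2 (the variance needs two points).
    cost:
        ``"meanvar_normal"`` (default) or ``"poisson"`` for sensitivity
        analysis.
    var_floor:
        Variance floor for degenerate (near-constant) segments; the
        Gaussian cost is evaluated at this variance when the segment MLE
        falls below it.  The default 0.25 sits below the granularity of
        integer counts while keeping constant pairs from dominating the
        objective.

    Attributes (after :meth:`fit`)
    ------------------------------
    breakpoints_ : list[int]
        1-based segment end positions, last = series length.
    segments_ : pandas.DataFrame
        Per-segment start/end, n, mean, SD.
    total_cost_ : float
        Penalized objective at the optimum.
    """

    def __init__(
        self,
        penalty: float | str = "MBIC",
        minseglen: int = 2,
        cost: str = "meanvar_normal",
        var_floor: float = 0.25,
    ):
        self.penalty = penalty
        self.minseglen = minseglen
        self.cost = cost
        self.var_floor = var_floor

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        n = len(x)
        if n < 2 * self.minseglen:
            raise ValueError(
                f"series of length {n} is shorter than 2*minseglen={2 * self.minseglen}"
            )
        beta, pen_name, seglen_term = _resolve_penalty(self.penalty, n)
        costfn = _COSTS[self.cost](x, var_floor=self.var_floor, seglen_term=seglen_term)
        m = self.minseglen
        # pruning slack: the MBIC log-seglen term is not subadditive, but
        # log n1 + log n2 >= log(n1 + n2) + log(4/n) for n1 + n2 <= n
        K = np.log(4.0 / n) if seglen_term else 0.0

        # F[t] = optimal penalized cost of x[0:t]; candidate last-change positions
        F = np.full(n + 1, np.inf)
        F[0] = -beta  # so each segment contributes cost + beta uniformly
        last = np.zeros(n + 1, dtype=int)
        candidates = [0]
        # a candidate pruned at time t is dominated by a change at t, which
        # is only available for ends >= t + m: delay its removal until then
        expire: dict[int, int] = {}
        for t in range(m, n + 1):
            candidates = [s for s in candidates if expire.get(s, n + 1) > t]
            best, arg = np.inf, 0
            for s in candidates:
                if t - s < m:
                    continue
                v = F[s] + costfn.cost(s, t) + beta
                if v < best:
                    best, arg = v, s
            F[t] = best
            last[t] = arg
            for s in candidates:
                if t - s >= m and s not in expire and F[s] + costfn.cost(s, t) + K > F[t]:
                    expire[s] = t + m
            candidates.append(t)  # a change at t is a candidate start for later ends
        # backtrack
        bps = []
        t = n
        while t > 0:
            bps.append(t)
            t = last[t]
        bps = sorted(bps)

        self.breakpoints_ = [int(b) for b in bps]
        self.penalty_value_ = float(beta)
        self.penalty_name_ = pen_name
        self.total_cost_ = float(F[n])
        self.n_changepoints_ = len(bps) - 1
        self.segments_ = _segment_table(x, bps, None)
        self._x = x
        return self

    def predict(self, X=None) -> list[int]:
        """Return the fitted breakpoints (sklearn-style accessor)."""
        return self.breakpoints_


def pelt_meanvar(
    series: MonthlySeries | Sequence[float],
    penalty: float | str = "MBIC",
    minseglen: int = 2,
    cost: str = "meanvar_normal",
    var_floor: float = 0.25,
) -> ChangepointResult:
    """Detect changepoints by PELT; see :class:`PeltMeanVar`."""
    start = country = None
    x = series
    if isinstance(series, MonthlySeries):
        start, country, x = series.start, series.country, series.counts
    est = PeltMeanVar(
        penalty=penalty, minseglen=minseglen, cost=cost, var_floor=var_floor
    ).fit(x)
    return ChangepointResult(
        breakpoints=est.breakpoints_,
        segments=_segment_table(np.asarray(x, float), est.breakpoints_, start),
        penalty=est.penalty_value_,
        penalty_name=est.penalty_name_,
        cost_name=cost,
        total_cost=est.total_cost_,
        start=start,
        country=country,
    )


def optimal_partition_oracle(
    series: MonthlySeries | Sequence[float],
    penalty: float | str = "MBIC",
    minseglen: int = 2,
    cost: str = "meanvar_normal",
    var_floor: float = 0.25,
) -> ChangepointResult:
    """Exhaustive O(n^2) optimal partitioning (no pruning); test oracle for PELT."""
    start = country = None
    x = series
    if isinstance(series, MonthlySeries):
        start, country, x = series.start, series.country, series.counts
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n > 500:
        raise ValueError("oracle limited to length <= 500")
    if n < minseglen:
        raise ValueError("series shorter than minseglen")
    beta, pen_name, seglen_term = _resolve_penalty(penalty, n)
    costfn = _COSTS[cost](x, var_floor=var_floor, seglen_term=seglen_term)

    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    for t in range(minseglen, n + 1):
        for s in range(0, t - minseglen + 1):
            if s != 0 and s < minseglen:
                continue
            if not np.isfinite(F[s]):
                continue
            v = F[s] + costfn.cost(s, t) + beta
            if v < F[t]:
                F[t], last[t] = v, s
    bps = []
    t = n
    while t > 0:
        bps.append(t)
        t = last[t]
    bps = sorted(bps)
    return ChangepointResult(
        breakpoints=[int(b) for b in bps],
        segments=_segment_table(x, bps, start),
        penalty=float(beta),
        penalty_name=pen_name,
        cost_name=cost,
        total_cost=float(F[n]),
        start=start,
        country=country,
    )


def segment_stats(
    series: MonthlySeries | Sequence[float], breakpoints: Sequence[int]
) -> pd.DataFrame:
    """Arithmetic mean and sample SD (n-1 denominator) per segment.

    ``breakpoints`` are 1-based segment end positions; the final position
    must equal the series length.  Single-month segments report a
    missing SD.
    """
    start = None
    x = series
    if isinstance(series, MonthlySeries):
        start, x = series.start, series.counts
    x = np.asarray(x, dtype=float)
    bps = list(map(int, breakpoints))
    if not bps or bps[-1] != len(x) or any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise ValueError("breakpoints must be increasing and end at the series length")
    return _segment_table(x, bps, start)
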