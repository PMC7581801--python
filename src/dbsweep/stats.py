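"""Inference layer: Pearson correlation with exact small-n significance and
paired waveform comparisons.

Correlations are computed on per-level cohort means against the physical
condition value (amplitude multiplier or frequency), so ``n`` equals the
number of levels and the t test has ``n - 2`` degrees of freedom. All
p-values are two-tailed and reported raw (no multiplicity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "pearson",
    "p_from_r",
    "waveform_ttest",
    "level_means",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    t_stat: float
    df: int
    p_two_tailed: float


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_two_tailed: float
    degenerate: bool = False  # zero-variance differences with non-zero mean


def _t_sf_df3(t: float) -> float:
    """Upper tail of Student's t with 3 df, closed form.

    ``S(t) = 1/2 - (1/pi) * [ t / (sqrt(3) * (1 + t^2/3)) + arctan(t/sqrt(3)) ]``
    """
    x = t / math.sqrt(3.0)
    return 0.5 - (x / (1.0 + x * x) + math.atan(x)) / math.pi


def p_from_r(rho: float, n: int) -> float:
    """Two-tailed p-value of a Pearson coefficient under the null, t-distributed.

    ``t = |rho| * sqrt((n-2) / (1 - rho^2))`` with ``n - 2`` df. The 3-df
    case uses the exact closed form; other df use the numerical tail.
    """
    if n < 3:
        raise DomainError("need n >= 3")
    if not abs(rho) < 1.0:
        raise DomainError("|rho| must be < 1")
    df = n - 2
    t = abs(rho) * math.sqrt(df / (1.0 - rho * rho))
    if df == 3:
        sf = _t_sf_df3(t)
    else:
        sf = float(sps.t.sf(t, df))
    return 2.0 * sf


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation of ``n`` paired observations with its
    two-tailed significance (see :func:`p_from_r`)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise DomainError("need n >= 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise DomainError("correlation undefined for a constant series")
    rho = float(np.dot(xc, yc) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    df = n - 2
    if abs(rho) >= 1.0 - 1e-15:
        return CorrelationResult(rho=rho, n=n, t_stat=math.inf, df=df, p_two_tailed=0.0)
    t = abs(rho) * math.sqrt(df / (1.0 - rho * rho))
    return CorrelationResult(rho=rho, n=n, t_stat=t, df=df, p_two_tailed=p_from_r(rho, n))


def waveform_ttest(
    a: Sequence[float], b: Sequence[float], paired: bool = True
) -> TTestResult:
    """Two-tailed t test between matched conditions.

    Paired by default (the same animals underwent every waveform); set
    ``paired=False`` for Welch's unequal-variance two-sample test.
    Zero-variance paired differences are reported as ``p = 1`` when the mean
    difference is zero, otherwise as a degenerate ``p -> 0`` result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise DomainError("paired test needs equal-length, matched samples")
        n = a.size
        if n < 2:
            raise DomainError("need n >= 2 pairs")
        d = a - b
        sd = float(d.std(ddof=1))
        df = n - 1
        if sd == 0.0:
            if float(d.mean()) == 0.0:
                return TTestResult(0.0, df, 1.0)
            return TTestResult(math.copysign(math.inf, d.mean()), df, 0.0, degenerate=True)
        res = sps.ttest_rel(a, b)
        return TTestResult(float(res.statistic), df, float(res.pvalue))
    if a.size < 2 or b.size < 2:
        raise DomainError("need n >= 2 per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), int(res.df), float(res.pvalue))


def level_means(
    table: pd.DataFrame,
    level_col: str = "level",
    value_col: str = "value",
    order: Sequence | None = None,
) -> pd.DataFrame:
    """Per-level cohort mean, SD (ddof=1) and available-case n.

    ``order`` fixes the row order (protocol order); every requested level
    must be present.
    """
    grouped = table.groupby(level_col)[value_col]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    if order is not None:
        missing = [lv for lv in order if lv not in set(out[level_col])]
        if missing:
            raise DomainError(f"levels with no observations: {missing}")
        out = (
            out.set_index(level_col).loc[list(order)].reset_index()
        )
    return out
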