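"""Group statistics and two-sample t tests for the error-injection study."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupStats:
    """n, arithmetic mean and sample (n-1) standard deviation, degrees."""

    n: int
    mean: float
    sd: float

    def __str__(self) -> str:
        return f"{self.mean:.1f} ± {self.sd:.1f}° (n={self.n})"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (report-table convention)."""
    scale = 10.0**ndigits
    return float(np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x))


def group_stats(values) -> GroupStats:
    """Mean ± sample standard deviation of a list of degree-valued measurements."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a sample standard deviation")
    return GroupStats(n=int(x.size), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


def two_sample_t(x, y, equal_variance: bool = True) -> TTestResult:
    """Independent two-sample t test, two-sided.

    Pooled-variance Student form by default (equal group sizes and comparable
    spreads in the study design); Welch with ``equal_variance=False``.
    Degenerate zero-variance groups: equal means give t = 0, p = 1; unequal
    means are an error (the statistic is infinite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        if np.mean(x) == np.mean(y):
            return TTestResult(t=0.0, df=float(x.size + y.size - 2), p=1.0)
        raise ValueError("zero variance with unequal means: t is infinite")
    if equal_variance:
        nx, ny = x.size, y.size
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        p = 2.0 * sps.t.sf(abs(t), df)
        return TTestResult(t=float(t), df=float(df), p=float(p))
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
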