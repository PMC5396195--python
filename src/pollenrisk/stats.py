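"""Simple ordinary least squares with F-test, R² and Gaussian AIC.

Implemented directly from the normal equations (rather than delegating to a
model-fitting library) so the AIC convention is fixed and testable:
aic = n·ln(RSS/n) + 2k with k = 3 (slope, intercept, error variance), the
additive constant omitted consistently.  Only AIC *differences* are ever
used, which are invariant to that constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["ols", "RegressionResult"]

_RSS_FLOOR = 1e-300  # guards log(0) on exact fits; AIC then ~ -inf in effect


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]  # (1, n - 2)
    p_value: float
    aic: float
    n: int


def ols(x, y) -> RegressionResult:
    """Least-squares fit of ``y = intercept + slope * x``.

    The p-value comes from the F(1, n−2) distribution.  Requires n >= 3 and
    non-constant x.  A constant y (zero total sum of squares) is reported as
    r_squared 0, F 0, p 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("x is constant; slope is not identifiable")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rss = float((resid**2).sum())
    tss = float(((y - ybar) ** 2).sum())

    if tss == 0:
        r2, f, p = 0.0, 0.0, 1.0
    elif rss <= tss * 1e-15:  # numerically exact fit
        r2, f, p = 1.0, math.inf, 0.0
    else:
        r2 = 1.0 - rss / tss
        f = (tss - rss) / (rss / (n - 2))
        p = float(_sps.f.sf(f, 1, n - 2))
    aic = n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * 3
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        f_stat=f,
        df=(1, n - 2),
        p_value=p,
        aic=aic,
        n=n,
    )
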