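"""Trait regressions: per-species Rd–A_max lines and a slope-equality test.

Dark respiration scales nearly linearly with light-saturated photosynthesis
within a species; whether two species share that scaling is tested with a
dummy-variable multiple regression:

    Rd = b0 + b1·A_max + b2·d1 + b3·(A_max·d1)

where d1 is 0 for the reference species (the wintergreen, "Dpm") and 1 for
the comparison species ("koreana").  b1 is the reference slope, b3 the slope
difference; the t-test of H0: b3 = 0 (two-sided, n − 4 residual degrees of
freedom) is the planned slope-equality contrast.  b2 captures the intercept
offset (a difference in baseline respiration at equal A_max).

OLS is delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class GroupLineFit:
    """OLS line Rd = intercept + slope·A_max for one species group."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r2: float
    n: int


@dataclass
class SlopeTestResult:
    """Dummy-variable regression output for the slope-equality contrast.

    ``b1`` is the group-0 slope, ``b3`` the slope difference so the group-1
    slope is ``b1 + b3``; ``p_interaction`` is the two-sided p-value of
    H0: b3 = 0.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    se: tuple[float, float, float, float]
    t_interaction: float
    p_interaction: float
    line_group0: tuple[float, float]
    line_group1: tuple[float, float]
    n: int
    r2: float


def fit_group_line(amax, rd) -> GroupLineFit:
    """OLS of Rd on A_max for one group (≥ 3 points, nonzero A_max spread)."""
    amax = np.asarray(amax, dtype=float)
    rd = np.asarray(rd, dtype=float)
    if amax.size < 3:
        raise ValueError("need at least 3 rows per group")
    if np.ptp(amax) == 0:
        raise ValueError("zero variance in amax")
    res = sm.OLS(rd, sm.add_constant(amax)).fit()
    return GroupLineFit(intercept=float(res.params[0]), slope=float(res.params[1]),
                        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
                        r2=float(res.rsquared), n=int(amax.size))


def slope_equality_test(table: pd.DataFrame) -> SlopeTestResult:
    """Test equality of the Rd–A_max slopes of the two groups.

    ``table`` needs columns ``group`` (0/1), ``amax`` and ``rd``, with at
    least 3 rows per group.
    """
    for col in ("group", "amax", "rd"):
        if col not in table.columns:
            raise ValueError(f"trait table missing column: {col}")
    g = table["group"].to_numpy()
    if not set(np.unique(g)) <= {0, 1} or len(np.unique(g)) < 2:
        raise ValueError("table must contain both groups coded 0 and 1")
    if (g == 0).sum() < 3 or (g == 1).sum() < 3:
        raise ValueError("need at least 3 rows in each group")
    amax = table["amax"].to_numpy(dtype=float)
    rd = table["rd"].to_numpy(dtype=float)
    d1 = g.astype(float)
    X = np.column_stack([np.ones_like(amax), amax, d1, amax * d1])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("singular dummy-variable design")
    res = sm.OLS(rd, X).fit()
    b0, b1, b2, b3 = (float(v) for v in res.params)
    return SlopeTestResult(
        b0=b0, b1=b1, b2=b2, b3=b3,
        se=tuple(float(v) for v in res.bse),
        t_interaction=float(res.tvalues[3]),
        p_interaction=float(res.pvalues[3]),
        line_group0=(b0, b1),
        line_group1=(b0 + b2, b1 + b3),
        n=int(amax.size), r2=float(res.rsquared))
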