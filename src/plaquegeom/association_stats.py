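"""Linear and power-law regression with significance classification.

Pairs of geometric parameters (volume, surface area, length, surface
distance, cross-section area/diameter) are related across objects of
different sizes.  Two models are fitted:

* simple linear regression ``y = a + b x`` with the Pearson correlation
  ``r``, ``R^2 = r^2`` and the two-sided p-value of the t statistic
  ``r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom;
* the allometric power law ``y = c x^e``, fitted by nonlinear least
  squares in the original scale (initialized from log-log OLS) so its
  ``R^2 = 1 - SS_res/SS_tot`` is directly comparable with the linear
  one.  The log-log OLS exponent is also reported for transparency.

A linear relationship is classified *significant* when ``r > 0.5`` (so
``R^2 > 0.25``) and ``p < 0.05``, and *strong* when ``r > 0.8``
(``R^2 > 0.64``) and ``p < 0.05`` — strict inequalities at every
threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RegressionResult",
    "RelationshipClass",
    "linear_fit",
    "power_fit",
    "classify",
    "pairwise_matrix",
    "matrix_to_frame",
]


@dataclass(frozen=True)
class RegressionResult:
    """One regression fit.

    For ``kind='linear'``: ``coef`` is the slope, ``second`` the
    intercept, ``pearson_r`` the correlation.  For ``kind='power'``:
    ``coef`` is the multiplier c, ``second`` the exponent e,
    ``pearson_r`` the correlation between fitted and observed values,
    and ``loglog_exponent`` the log-log OLS initializer exponent.
    ``r_squared`` is always computed in the original scale; for power
    fits it can be negative (no floor is applied, to keep linear and
    power fits comparable).
    """

    kind: Literal["linear", "power"]
    coef: float
    second: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int
    loglog_exponent: float | None = None
    converged: bool = True

    @property
    def slope(self) -> float:
        if self.kind != "linear":
            raise AttributeError("slope defined for linear fits only")
        return self.coef

    @property
    def intercept(self) -> float:
        if self.kind != "linear":
            raise AttributeError("intercept defined for linear fits only")
        return self.second

    @property
    def exponent(self) -> float:
        if self.kind != "power":
            raise AttributeError("exponent defined for power fits only")
        return self.second

    @property
    def multiplier(self) -> float:
        if self.kind != "power":
            raise AttributeError("multiplier defined for power fits only")
        return self.coef


@dataclass(frozen=True)
class RelationshipClass:
    """Strength class of a linear relationship: none, significant, strong."""

    label: Literal["none", "significant", "strong"]

    @property
    def marker(self) -> str:
        return {"none": "", "significant": "*", "strong": "**"}[self.label]


def _validate_xy(x, y, positive: bool = False) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if positive and (np.any(x <= 0) or np.any(y <= 0)):
        raise ValueError("power-law fitting requires strictly positive x and y")
    return x, y


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares ``y = a + b x`` with Pearson r and p."""
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("x is constant: linear fit is degenerate")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    return RegressionResult(
        kind="linear",
        coef=float(res.slope),
        second=float(res.intercept),
        pearson_r=r,
        r_squared=r * r,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def power_fit(x, y) -> RegressionResult:
    """Nonlinear least squares ``y = c x^e`` in the original scale.

    Initialized from log-log OLS.  If the NLS iteration fails to
    converge the initializer is returned with ``converged=False``.  The
    p-value reported is that of the Pearson correlation between fitted
    and observed values (the original-scale goodness of the power
    curve).
    """
    x, y = _validate_xy(x, y, positive=True)
    ll = stats.linregress(np.log(x), np.log(y))
    c0, e0 = math.exp(ll.intercept), float(ll.slope)

    def model(xv, c, e):
        return c * np.power(xv, e)

    converged = True
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=[c0, e0], maxfev=10000)
        c, e = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        c, e = c0, e0

    fitted = model(x, c, e)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.ptp(fitted) > 0 and np.ptp(y) > 0:
        rr = stats.pearsonr(fitted, y)
        r, p = float(rr.statistic), float(rr.pvalue)
    else:
        r, p = 0.0, 1.0
    return RegressionResult(
        kind="power",
        coef=c,
        second=e,
        pearson_r=r,
        r_squared=r2,
        p_value=p,
        n=int(x.size),
        loglog_exponent=e0,
        converged=converged,
    )


def classify(res: RegressionResult) -> RelationshipClass:
    """Strength class from (r, p): strict thresholds 0.5 / 0.8 and 0.05."""
    r, p = res.pearson_r, res.p_value
    if r > 0.8 and p < 0.05:
        return RelationshipClass("strong")
    if r > 0.5 and p < 0.05:
        return RelationshipClass("significant")
    return RelationshipClass("none")


def pairwise_matrix(
    table: pd.DataFrame, variables: list[str]
) -> dict[tuple[str, str], tuple[RegressionResult, RelationshipClass]]:
    """All pairwise linear fits among ``variables`` of a table.

    Returns the upper triangle as a dict keyed by (var_i, var_j) in the
    order given; k variables yield k(k-1)/2 cells.
    """
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    out: dict[tuple[str, str], tuple[RegressionResult, RelationshipClass]] = {}
    for vi, vj in itertools.combinations(variables, 2):
        res = linear_fit(table[vi].to_numpy(), table[vj].to_numpy())
        out[(vi, vj)] = (res, classify(res))
    return out


def matrix_to_frame(
    matrix: dict[tuple[str, str], tuple[RegressionResult, RelationshipClass]],
) -> pd.DataFrame:
    """Serialize a pairwise matrix to the upper-triangular table layout.

    Cells read ``r = ..., p = ...`` with ``*`` marking significant and
    ``**`` strong relationships.
    """
    variables: list[str] = []
    for vi, vj in matrix:
        for v in (vi, vj):
            if v not in variables:
                variables.append(v)
    frame = pd.DataFrame("", index=variables, columns=variables, dtype=object)
    for (vi, vj), (res, cls) in matrix.items():
        p_txt = "p<0.001" if res.p_value < 0.001 else f"p={res.p_value:.3f}"
        frame.loc[vi, vj] = f"r={res.pearson_r:.3f}, {p_txt}{cls.marker}"
    return frame
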