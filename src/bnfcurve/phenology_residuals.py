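"""Phenology de-trending and residual regressions against RAU at R6.

In a multi-environment trial the maturity group assigned to each site
confounds crop phenology (thermal time to R6 spans roughly 900-1700 °Cd)
with every agronomic outcome.  Traits (seed yield, harvest index, seed oil)
are therefore first de-trended with a continuous two-segment ("bilinear")
model of trait vs thermal time to R6,

    Y = a * X + b                  for X <  TT_o
    Y = a * TT_o + b + d * (X - TT_o)  for X >= TT_o

with continuity enforced at the breakpoint TT_o (four parameters:
a, b, d, TT_o).  The residuals of that model are then regressed on RAU_R6,
at the mean (OLS) and at boundary quantiles (tau = 0.99 and 0.01, check-loss
quantile regression) to trace the upper and lower response envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

from .errors import DomainError, InsufficientDataError

__all__ = [
    "BilinearFit",
    "ResidualRegression",
    "fit_bilinear",
    "residual_mean_regression",
    "residual_quantile_regression",
]


@dataclass
class BilinearFit:
    """Continuous two-segment linear trend of a trait on thermal time to R6.

    ``a``/``b`` are slope and intercept of the first segment, ``d`` is the
    slope beyond the breakpoint ``tt_o``; the two segments meet at ``tt_o``
    by construction.
    """

    a: float
    b: float
    d: float
    tt_o: float
    residuals: np.ndarray = field(repr=False)
    r2: float
    sse: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        hinge = np.maximum(x - self.tt_o, 0.0)
        out = self.b + self.a * np.minimum(x, self.tt_o) + self.d * hinge
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ResidualRegression:
    """Slope of de-trended trait residuals against RAU_R6.

    ``tau`` is "mean" for the OLS fit or the quantile level; ``p_value`` is
    reported for the mean fit only (two-sided test of slope = 0).
    """

    tau: float | str
    slope: float
    intercept: float
    p_value: float | None = None
    n: int = 0

    def predict(self, rau):
        return self.intercept + self.slope * np.asarray(rau, dtype=float)


def _hinge_design(x: np.ndarray, tt_o: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), np.minimum(x, tt_o), np.maximum(x - tt_o, 0.0)]
    )


def fit_bilinear(x, y, n_trim: int = 2) -> BilinearFit:
    """Fit the continuous two-segment model by profiling the breakpoint.

    Candidate breakpoints are the observed x values with ``n_trim``
    extremes excluded at each end; for each candidate the remaining
    parameters (a, b, d) are solved by linear least squares on the hinge
    basis, and the global SSE minimizer is returned.  The profiled grid
    makes the fit deterministic and reproducible; with ~90 site x treatment
    means the grid resolution is ample.

    Raises
    ------
    InsufficientDataError
        with fewer than 6 points or fewer than 3 on either side of every
        candidate breakpoint.
    DomainError
        if trimming leaves no interior candidate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 6:
        raise InsufficientDataError(f"need >= 6 points for a bilinear fit, got {x.size}")
    candidates = np.unique(x)[n_trim:-n_trim] if n_trim else np.unique(x)
    # keep candidates with >= 3 points strictly below and >= 3 at/above
    candidates = [
        c for c in candidates
        if np.sum(x < c) >= 3 and np.sum(x >= c) >= 3
    ]
    if not candidates:
        raise DomainError("no interior breakpoint candidate after trimming")

    best = None
    for c in candidates:
        X = _hinge_design(x, c)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, c, beta, resid)

    sse, tt_o, beta, resid = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return BilinearFit(
        a=float(beta[1]),
        b=float(beta[0]),
        d=float(beta[2]),
        tt_o=float(tt_o),
        residuals=resid,
        r2=r2,
        sse=sse,
    )


def residual_mean_regression(residuals, rau_r6) -> ResidualRegression:
    """OLS regression of de-trended residuals on RAU_R6 with a slope test."""
    r = np.asarray(residuals, dtype=float)
    u = np.asarray(rau_r6, dtype=float)
    if r.size != u.size:
        raise DomainError("residuals and rau_r6 must have equal length")
    if r.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {r.size}")
    if np.ptp(u) == 0:
        raise DomainError("rau_r6 has zero variance; slope undefined")
    X = sm.add_constant(u)
    fit = sm.OLS(r, X).fit()
    return ResidualRegression(
        tau="mean",
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]),
        n=int(r.size),
    )


def residual_quantile_regression(residuals, rau_r6, tau: float) -> ResidualRegression:
    """Check-loss quantile regression of residuals on RAU_R6 at level tau.

    Minimizes sum rho_tau(resid - alpha - beta * rau).  Extreme quantiles
    (0.01 / 0.99) trace the boundaries of the response; they are unstable
    below ~50 points and refused below 20.
    """
    if not (0.0 < tau < 1.0):
        raise DomainError(f"tau must lie in (0, 1), got {tau}")
    r = np.asarray(residuals, dtype=float)
    u = np.asarray(rau_r6, dtype=float)
    if r.size < 20:
        raise InsufficientDataError(
            f"quantile regression needs >= 20 points, got {r.size}"
        )
    if np.ptp(u) == 0:
        raise DomainError("rau_r6 has zero variance; slope undefined")
    X = sm.add_constant(u)
    fit = QuantReg(r, X).fit(q=tau, max_iter=5000)
    return ResidualRegression(
        tau=tau,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=None,
        n=int(r.size),
    )
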