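"""Beta growth function for seasonal RAU trajectories and its derived traits.

The seasonal rise of the relative abundance of ureides is modelled with the
three-parameter beta growth function of determinate growth:

    RAU(t) = RAU_max * (1 + (t_max - t) / (t_max - t_m)) * (t / t_max)^(t_max / (t_max - t_m))

where ``t`` is thermal time from V2 (°Cd), ``RAU_max`` is the peak RAU
reached at ``t_max``, and ``t_m`` is the thermal time of the maximum growth
rate (the inflection point).  The curve is 0 at t = 0, rises sigmoidally,
peaks at exactly RAU_max when t = t_max, and declines beyond the peak.

The analytical first derivative gives the instantaneous fixation rate:

    rate(t) = max_rate * ((t_max - t) / (t_max - t_m)) * (t / t_m)^(t_m / (t_max - t_m))

with the closed-form maximum rate attained at t = t_m:

    max_rate = RAU_max * (2 t_max - t_m) / (t_max (t_max - t_m)) * (t_m / t_max)^(t_m / (t_max - t_m))

At t_m = 0 the 0^0 power terms are taken as 1 by continuous limit (the
low-fixation group fits hit that boundary).

Derived traits: t_half (thermal time at 50% of RAU_max, the unique root on
(0, t_max) because the curve is strictly increasing there), and the area
under the fitted curve (AUC) integrating season-long fixation, reported raw
(% °Cd) and normalized to the dataset maximum.

Treatment effects on whole curves are compared with the small-sample
Akaike information criterion (AICc): one shared parameter triple fitted to
pooled data against separate triples per group, counting the error
variance as a parameter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
import numpy as np
from scipy import optimize
from scipy.integrate import simpson

from .errors import (
    DegenerateParameterError,
    DomainError,
    FitConvergenceError,
    InsufficientDataError,
)

__all__ = [
    "RauObservation",
    "BetaCurveFit",
    "AiccComparison",
    "beta_rau",
    "rau_rate",
    "max_rate",
    "t_half",
    "auc",
    "fit_beta",
    "aicc",
    "compare_fits_aicc",
]


@dataclass(frozen=True)
class RauObservation:
    """One RAU reading (percent) at thermal time t (°Cd from V2)."""

    t: float
    rau: float
    group: str | None = None
    treatment: str | None = None

    def __post_init__(self):
        if self.t < 0:
            raise DomainError(f"thermal time must be >= 0, got {self.t}")
        if not (0.0 <= self.rau <= 100.0):
            raise DomainError(f"RAU must lie in [0, 100], got {self.rau}")


def _check_params(rau_max: float, t_m: float, t_max: float) -> None:
    if t_m == t_max:
        raise DegenerateParameterError("t_m == t_max collapses the beta function")
    if not (0 <= t_m < t_max):
        raise DegenerateParameterError(
            f"require 0 <= t_m < t_max, got t_m={t_m}, t_max={t_max}"
        )
    if rau_max < 0:
        raise DegenerateParameterError(f"rau_max must be >= 0, got {rau_max}")


def _params_of(params) -> tuple[float, float, float]:
    """Accept a BetaCurveFit, a (rau_max, t_m, t_max) triple, or kwargs-like."""
    if isinstance(params, BetaCurveFit):
        return params.rau_max, params.t_m, params.t_max_
    rau_max, t_m, t_max = params
    return float(rau_max), float(t_m), float(t_max)


def beta_rau(t, params):
    """Evaluate the beta growth function at thermal time(s) t.

    Equals 0 at t = 0 and exactly RAU_max at t = t_max.  Vectorized over t.
    """
    rau_max, t_m, t_max = _params_of(params)
    _check_params(rau_max, t_m, t_max)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("thermal time must be >= 0")
    span = t_max - t_m
    with np.errstate(divide="ignore", invalid="ignore"):
        power = np.where(t_arr > 0, (t_arr / t_max) ** (t_max / span), 0.0)
    out = rau_max * (1.0 + (t_max - t_arr) / span) * power
    return float(out) if out.ndim == 0 else out


def max_rate(params) -> float:
    """Closed-form maximum RAU rate (% °Cd^-1), attained at t = t_m.

    At t_m = 0 the power term is 1 by continuous limit.
    """
    rau_max, t_m, t_max = _params_of(params)
    _check_params(rau_max, t_m, t_max)
    span = t_max - t_m
    power = 1.0 if t_m == 0 else (t_m / t_max) ** (t_m / span)
    return rau_max * (2.0 * t_max - t_m) / (t_max * span) * power


def rau_rate(t, params):
    """Instantaneous RAU rate (% °Cd^-1): the derivative of the growth curve.

    Zero at t = t_max and negative beyond it (the post-peak decline).
    Vectorized over t.
    """
    rau_max, t_m, t_max = _params_of(params)
    _check_params(rau_max, t_m, t_max)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("thermal time must be >= 0")
    span = t_max - t_m
    if t_m == 0:
        power = np.ones_like(t_arr)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            power = np.where(t_arr > 0, (t_arr / t_m) ** (t_m / span), 0.0)
    out = max_rate((rau_max, t_m, t_max)) * ((t_max - t_arr) / span) * power
    return float(out) if out.ndim == 0 else out


def t_half(params, tol: float = 1e-9) -> float:
    """Thermal time (°Cd) at which the curve reaches 50% of RAU_max.

    Unique root of RAU(t) = RAU_max / 2 on (0, t_max): the curve is strictly
    increasing there, from 0 to RAU_max.  Solved by Brent's method to a
    residual below ``tol`` of normalized RAU.
    """
    rau_max, t_m, t_max = _params_of(params)
    _check_params(rau_max, t_m, t_max)
    if rau_max == 0:
        raise DegenerateParameterError("t_half undefined for a zero-amplitude curve")

    def f(t):
        return beta_rau(t, (rau_max, t_m, t_max)) / rau_max - 0.5

    return float(optimize.brentq(f, 1e-12 * t_max, t_max, xtol=tol * t_max, rtol=1e-14))


def auc(params, t_end: float, dataset_max: float | None = None,
        n_panels: int = 2000) -> tuple[float, float]:
    """Area under the fitted RAU curve on [0, t_end].

    Integrates max(RAU(t), 0) by composite Simpson quadrature on
    ``n_panels`` panels (default 2000).  Returns ``(auc_raw, auc_rel)``
    where ``auc_raw`` is in % °Cd and ``auc_rel`` is normalized by
    ``dataset_max`` (the largest raw AUC in the data set, so the maximal
    curve scores exactly 1).  Without ``dataset_max`` the curve is
    self-normalized: rel = 1 for any non-degenerate curve, 0 for a flat one.
    """
    if t_end <= 0:
        raise DomainError(f"t_end must be > 0, got {t_end}")
    rau_max, t_m, t_max = _params_of(params)
    if rau_max == 0:
        return 0.0, 0.0
    grid = np.linspace(0.0, t_end, n_panels + 1)
    vals = np.maximum(beta_rau(grid, (rau_max, t_m, t_max)), 0.0)
    raw = float(simpson(vals, x=grid))
    if dataset_max is None:
        dataset_max = raw
    rel = 0.0 if raw == 0 else raw / dataset_max
    return raw, rel


@dataclass
class BetaCurveFit:
    """A fitted beta growth curve with uncertainty and derived traits.

    ``syx`` is the residual standard deviation sqrt(SSE / (n - 3)), the
    goodness-of-fit measure reported alongside R^2.
    """

    rau_max: float
    t_m: float
    t_max_: float
    se_rau_max: float = float("nan")
    se_t_m: float = float("nan")
    se_t_max: float = float("nan")
    r2: float = float("nan")
    syx: float = float("nan")
    n_obs: int = 0
    sse: float = float("nan")
    converged: bool = True
    at_boundary: bool = False

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.rau_max, self.t_m, self.t_max_)

    # -- derived traits -------------------------------------------------
    @property
    def max_rate(self) -> float:
        return max_rate(self.params)

    @property
    def t_half(self) -> float:
        return t_half(self.params)

    def auc(self, t_end: float, dataset_max: float | None = None):
        return auc(self.params, t_end, dataset_max)

    def predict(self, t):
        return beta_rau(t, self.params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["max_rate"] = self.max_rate
        d["t_half"] = self.t_half
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _obs_arrays(obs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obs, tuple) and len(obs) == 2:
        t, y = obs
        return np.asarray(t, dtype=float), np.asarray(y, dtype=float)
    t = np.array([o.t for o in obs], dtype=float)
    y = np.array([o.rau for o in obs], dtype=float)
    return t, y


def fit_beta(obs, init: tuple[float, float, float] | None = None) -> BetaCurveFit:
    """Least-squares fit of the beta growth function to RAU observations.

    ``obs`` is a sequence of :class:`RauObservation` or an ``(t, rau)``
    array pair.  Replicate-level points enter individually (no
    pre-averaging).  The fit minimizes unweighted SSE over
    (rau_max, t_m, t_max) with box constraints 0 < rau_max <= 110,
    0 <= t_m < t_max <= 1.5 * max(t).  Internally the model is
    reparameterized as (rau_max, frac, t_max) with t_m = frac * t_max and
    frac in [0, 0.995], so the ordering constraint holds throughout
    optimization; the standard error for t_m follows by the delta method
    from the covariance of (frac, t_max).

    Initialization (robust for sigmoidal data sampled at few stages):
    rau_max0 = max observed RAU, t_max0 = t at that maximum,
    t_m0 = 0.4 * t_max0.

    Raises
    ------
    InsufficientDataError
        with fewer than 4 observations or fewer than 2 distinct t.
    FitConvergenceError
        if the optimizer does not converge; carries the last parameters.
    """
    t, y = _obs_arrays(obs)
    n = t.size
    if n <= 3:
        raise InsufficientDataError(f"need >= 4 observations to fit 3 parameters, got {n}")
    if np.unique(t).size < 2:
        raise InsufficientDataError("observations must span at least 2 distinct thermal times")
    if np.ptp(y) == 0:
        raise InsufficientDataError("all RAU values identical; the curve is not identifiable")
    t_ub = 1.5 * float(t.max())
    FRAC_UB = 0.995

    if init is None:
        i_max = int(np.argmax(y))
        t_max0 = float(t[i_max]) if t[i_max] > 0 else float(np.max(t))
        init = (float(np.max(y)), 0.4 * t_max0, t_max0)
    rau0, tm0, tmax0 = init
    rau0 = float(np.clip(rau0, 1e-3, 110.0))
    tmax0 = float(np.clip(tmax0, 1.0, t_ub))
    frac0 = float(np.clip(tm0 / tmax0, 0.0, 0.9))

    def model(theta):
        rau_max, frac, t_max = theta
        span = t_max * (1.0 - frac)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            power = np.where(t > 0, (t / t_max) ** (t_max / span), 0.0)
        return rau_max * (1.0 + (t_max - t) / span) * power

    def residuals(theta):
        return model(theta) - y

    lower = np.array([1e-6, 0.0, 1.0])
    upper = np.array([110.0, FRAC_UB, t_ub])
    theta0 = np.clip(np.array([rau0, frac0, tmax0]), lower + 1e-12, upper - 1e-12)

    res = optimize.least_squares(
        residuals, theta0, bounds=(lower, upper), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    rau_max, frac, t_max = res.x
    t_m = frac * t_max
    if not res.success:
        raise FitConvergenceError(
            f"beta fit did not converge: {res.message}",
            last_params=(float(rau_max), float(t_m), float(t_max)),
        )

    sse = float(np.sum(res.fun**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    syx = float(np.sqrt(sse / (n - 3)))

    # asymptotic covariance from the Jacobian at the solution
    se = np.full(3, np.nan)
    se_tm = float("nan")
    dof = n - 3
    if dof > 0:
        J = res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (sse / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            # t_m = frac * t_max: delta method with gradient (t_max, frac)
            g = np.array([t_max, frac])
            blk = cov[np.ix_([1, 2], [1, 2])]
            se_tm = float(np.sqrt(max(g @ blk @ g, 0.0)))
        except np.linalg.LinAlgError:
            pass

    tol_b = 1e-6
    at_boundary = bool(
        rau_max >= upper[0] - tol_b
        or frac >= FRAC_UB - tol_b
        or t_max >= t_ub - tol_b
        or rau_max <= lower[0] + tol_b
    )

    return BetaCurveFit(
        rau_max=float(rau_max),
        t_m=float(t_m),
        t_max_=float(t_max),
        se_rau_max=float(se[0]),
        se_t_m=se_tm,
        se_t_max=float(se[2]),
        r2=r2,
        syx=syx,
        n_obs=int(n),
        sse=sse,
        converged=bool(res.success),
        at_boundary=at_boundary,
    )


def aicc(n: int, sse: float, k: int) -> float:
    """Small-sample Akaike information criterion for a least-squares model.

    AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n - k - 1), with k counting the
    error variance as a fitted parameter.
    """
    if n - k - 1 <= 0:
        raise InsufficientDataError(
            f"AICc requires n - k - 1 > 0 (n={n}, k={k})"
        )
    if sse <= 0:
        raise DomainError("AICc requires SSE > 0")
    return n * float(np.log(sse / n)) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class AiccComparison:
    """Shared-vs-separate curve comparison by AICc on pooled data."""

    aicc_shared: float
    aicc_separate: float
    delta: float  # aicc_separate - aicc_shared
    preferred: str  # "shared" | "separate"
    evidence_ratio: float
    fit_shared: BetaCurveFit = field(compare=False, default=None)
    fit_a: BetaCurveFit = field(compare=False, default=None)
    fit_b: BetaCurveFit = field(compare=False, default=None)


def compare_fits_aicc(obs_a, obs_b) -> AiccComparison:
    """Test whether two observation sets need separate beta curves.

    The shared model fits one parameter triple to the pooled data
    (k = 3 + 1 for the error variance); the separate model fits one triple
    per set (k = 6 + 1).  Both AICc values are computed on the pooled n;
    the smaller wins and the evidence ratio exp(|delta| / 2) quantifies the
    preference.
    """
    ta, ya = _obs_arrays(obs_a)
    tb, yb = _obs_arrays(obs_b)
    pooled = (np.concatenate([ta, tb]), np.concatenate([ya, yb]))
    fit_shared = fit_beta(pooled)
    fit_a = fit_beta((ta, ya))
    fit_b = fit_beta((tb, yb))
    n = ta.size + tb.size
    a_shared = aicc(n, fit_shared.sse, k=4)
    a_sep = aicc(n, fit_a.sse + fit_b.sse, k=7)
    delta = a_sep - a_shared
    preferred = "separate" if a_sep < a_shared else "shared"
    return AiccComparison(
        aicc_shared=a_shared,
        aicc_separate=a_sep,
        delta=delta,
        preferred=preferred,
        evidence_ratio=float(np.exp(abs(delta) / 2.0)),
        fit_shared=fit_shared,
        fit_a=fit_a,
        fit_b=fit_b,
    )
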