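"""Thermal performance curve (TPC) fitting and niche metrics.

The growth-rate/temperature relation is modeled by the Blanchard curve

    mu(T) = mu_max * x**beta * exp(-beta * (x - 1)),   x = (Tmax - T)/(Tmax - Topt)

which equals ``mu_max`` at ``T = Topt``, falls to zero at ``T = Tmax`` and is
defined as zero above ``Tmax``.  Fitting is multistart nonlinear least
squares on an unconstrained internal parameterization; standard errors come
from the Jacobian-based covariance at the optimum via the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DataError, EstimationError, FitError

__all__ = [
    "GrowthTemperatureProfile",
    "ThermalCurveParams",
    "ThermalNiche",
    "blanchard_growth",
    "blanchard_rate",
    "fit_thermal_curve",
    "performance_range",
    "correlate_and_regress",
    "RegressionResult",
]


@dataclass(frozen=True)
class ThermalCurveParams:
    """Blanchard curve parameters with standard errors and fit diagnostics."""

    mu_max: float
    t_opt: float
    t_max: float
    beta: float
    se_mu_max: float = float("nan")
    se_t_opt: float = float("nan")
    se_t_max: float = float("nan")
    se_beta: float = float("nan")
    rss: float = float("nan")
    converged: bool = True
    strain_id: str = ""

    def __post_init__(self):
        if not self.t_max > self.t_opt:
            raise DataError(f"t_max ({self.t_max}) must exceed t_opt ({self.t_opt})")
        if not self.mu_max > 0:
            raise DataError("mu_max must be > 0")
        if not self.beta > 0:
            raise DataError("beta must be > 0")

    def predict(self, temperature):
        return blanchard_rate(temperature, self.mu_max, self.t_opt, self.t_max, self.beta)


@dataclass(frozen=True)
class GrowthTemperatureProfile:
    """Mean growth rates (with SEs) at a set of distinct temperatures."""

    strain_id: str
    temperatures: tuple
    mean_rates: tuple
    se_rates: tuple = ()

    def __post_init__(self):
        t = tuple(float(x) for x in self.temperatures)
        r = tuple(float(x) for x in self.mean_rates)
        s = tuple(float(x) for x in self.se_rates) if len(self.se_rates) else tuple(0.0 for _ in t)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "mean_rates", r)
        object.__setattr__(self, "se_rates", s)
        if len(t) != len(r) or len(t) != len(s):
            raise DataError("temperatures, rates and SEs must have equal length")
        if len(set(t)) != len(t):
            raise DataError("temperatures must be distinct")


@dataclass(frozen=True)
class ThermalNiche:
    """Temperature interval where predicted growth >= fraction * mu_max."""

    t_low: float
    t_high: float
    width: float
    performance_fraction: float = 0.8


def blanchard_rate(temperature, mu_max, t_opt, t_max, beta):
    """Blanchard growth rate; vectorized over ``temperature``.

    Returns 0 for temperatures above ``t_max`` (domain extension).
    """
    T = np.asarray(temperature, dtype=float)
    # log-space evaluation: beta*log(x) - beta*(x-1) peaks at 0 (x=1), so
    # exp cannot overflow for finite x; x <= 0 maps to rate 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x = (t_max - T) / (t_max - t_opt)
        logx = np.log(np.where(x > 0, x, 1.0))
        expo = np.clip(beta * logx - beta * (x - 1.0), -745.0, 0.0)
        val = mu_max * np.where(x > 0, np.exp(expo), 0.0)
    if np.ndim(temperature) == 0:
        return float(val)
    return val


def blanchard_growth(temperature, params: ThermalCurveParams):
    """Evaluate the curve described by a ThermalCurveParams object."""
    return blanchard_rate(temperature, params.mu_max, params.t_opt, params.t_max, params.beta)


# ---------------------------------------------------------------------------
# Fitting
#
# Internal parameterization (unconstrained):
#   theta = (log mu_max, t_opt, log(t_max - t_opt), log beta)

def _unpack(theta):
    # exp clamped so extreme optimizer proposals stay finite
    e = lambda v: math.exp(min(v, 700.0))
    return e(theta[0]), theta[1], theta[1] + e(theta[2]), e(theta[3])


def _residuals(theta, T, y, w):
    mu, topt, tmax, beta = _unpack(theta)
    return (blanchard_rate(T, mu, topt, tmax, beta) - y) * w


def _jacobian(theta, T, y, w):
    """Analytic Jacobian of the residuals w.r.t. the internal parameters."""
    mu, topt, tmax, beta = _unpack(theta)
    s = tmax - topt
    f = blanchard_rate(T, mu, topt, tmax, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (tmax - np.asarray(T, dtype=float)) / s
        logx = np.log(np.where(x > 0, x, 1.0))
        inv = np.where(x > 0, 1.0 / np.where(x > 0, x, 1.0), 0.0)
    J = np.empty((np.size(T), 4))
    with np.errstate(invalid="ignore", over="ignore"):
        J[:, 0] = f                                    # d/d log(mu_max)
        J[:, 1] = f * beta * (inv - 1.0) / s           # d/d t_opt
        J[:, 2] = f * beta * (inv - 1.0) * (1.0 - x)   # d/d log(tmax - topt)
        J[:, 3] = f * beta * (logx - x + 1.0)          # d/d log(beta)
    J[x <= 0] = 0.0
    return J * w[:, None]


def fit_thermal_curve(
    profile: GrowthTemperatureProfile,
    weighted: bool = False,
    max_iter: int = 500,
) -> ThermalCurveParams:
    """Fit the Blanchard curve to a growth/temperature profile.

    Minimizes the (optionally 1/SE^2-weighted) sum of squared residuals
    between observed mean rates and the model, using a multistart
    Levenberg-Marquardt-type search.  Standard errors are delta-method
    transforms of the Jacobian covariance, scaled by residual variance.

    Raises
    ------
    EstimationError
        Fewer than 5 distinct temperatures, or no positive rate.
    FitError
        Every start failed to produce a usable optimum.
    """
    T = np.asarray(profile.temperatures, dtype=float)
    y = np.asarray(profile.mean_rates, dtype=float)
    if T.size < 5:
        raise EstimationError(
            f"need >= 5 distinct temperatures for a 4-parameter fit, got {T.size}"
        )
    if not np.any(y > 0):
        raise EstimationError("no positive growth rate in profile")
    if weighted:
        se = np.asarray(profile.se_rates, dtype=float)
        se = np.where(se > 0, se, np.nanmin(se[se > 0]) if np.any(se > 0) else 1.0)
        w = 1.0 / se
    else:
        w = np.ones_like(y)

    t_best = float(T[np.argmax(y)])
    mu0 = float(max(y.max(), 1e-3))
    starts = []
    for topt0 in (t_best - 5.0, t_best, t_best + 5.0):
        for dt in (3.0, 8.0, 15.0):
            for beta0 in (0.5, 2.0, 5.0):
                starts.append(
                    np.array([math.log(mu0), topt0, math.log(dt), math.log(beta0)])
                )

    best = None
    rss_floor = 1e-12 * max(float(np.sum(y * y)), 1.0)
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                _residuals,
                theta0,
                jac=_jacobian,
                args=(T, y, w),
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_iter,
            )
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0] - 1e-14:
            best = (rss, res)
        if rss < rss_floor:  # numerically perfect fit; skip remaining starts
            break
    if best is None:
        raise FitError(f"all multistarts failed for strain {profile.strain_id!r}")
    rss, res = best
    mu, topt, tmax, beta = _unpack(res.x)

    # covariance of theta at the optimum, scaled by residual variance
    n, p = T.size, 4
    dof = max(n - p, 1)
    s2 = rss / dof
    J = res.jac
    try:
        cov_theta = s2 * np.linalg.inv(J.T @ J)
        # delta method to (mu_max, t_opt, t_max, beta)
        G = np.zeros((4, 4))
        G[0, 0] = mu                    # d mu / d theta0
        G[1, 1] = 1.0                   # d topt / d theta1
        G[2, 1] = 1.0                   # d tmax / d theta1
        G[2, 2] = tmax - topt           # d tmax / d theta2
        G[3, 3] = beta                  # d beta / d theta3
        cov_nat = G @ cov_theta @ G.T
        ses = np.sqrt(np.clip(np.diag(cov_nat), 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.full(4, np.nan)

    return ThermalCurveParams(
        mu_max=mu,
        t_opt=topt,
        t_max=tmax,
        beta=beta,
        se_mu_max=float(ses[0]),
        se_t_opt=float(ses[1]),
        se_t_max=float(ses[2]),
        se_beta=float(ses[3]),
        rss=rss,
        converged=bool(res.success),
        strain_id=profile.strain_id,
    )


def performance_range(params: ThermalCurveParams, fraction: float = 0.8) -> ThermalNiche:
    """Temperature interval where the curve is >= fraction * mu_max.

    The two bounds are found by bracketed root solving on either side of
    the optimum.
    """
    if not (0.0 < fraction <= 1.0):
        raise DataError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return ThermalNiche(params.t_opt, params.t_opt, 0.0, 1.0)
    target = fraction * params.mu_max

    def g(T):
        return blanchard_growth(T, params) - target

    # upper bound: between t_opt (g > 0) and t_max (g = -target < 0)
    t_high = optimize.brentq(g, params.t_opt, params.t_max, xtol=1e-10)
    # lower bound: walk down from t_opt until the curve drops below target
    lo = params.t_opt - (params.t_max - params.t_opt)
    while g(lo) > 0:
        lo = params.t_opt - 2.0 * (params.t_opt - lo)
    t_low = optimize.brentq(g, lo, params.t_opt, xtol=1e-10)
    return ThermalNiche(float(t_low), float(t_high), float(t_high - t_low), fraction)


@dataclass(frozen=True)
class RegressionResult:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    slope_se: float
    n: int

    def as_dict(self):
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "n": self.n,
        }


def correlate_and_regress(x, y) -> RegressionResult:
    """Pearson correlation (two-sided t test) plus OLS slope/intercept/SE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("constant input vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    lr = stats.linregress(x, y)
    return RegressionResult(
        pearson_r=float(r),
        p_value=float(p),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        slope_se=float(lr.stderr),
        n=int(x.size),
    )
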