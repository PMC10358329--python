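"""Damped Gauss–Newton (Levenberg–Marquardt) fitting of sigmoid time courses.

The optimizer is self-contained and derivative-free from the caller's
perspective: the Jacobian is a forward finite difference, and each iteration
solves the damped normal equations

    (JᵀJ + λ diag(JᵀJ)) δ = Jᵀ r

accepting a trial step only when the sum of squared residuals decreases
(λ shrinks on acceptance, grows on rejection — the classic Marquardt
schedule).  Trial parameter vectors that leave a model's valid domain or
produce non-finite predictions are treated as infinitely bad and rejected.

Quality metrics follow the usual nonlinear-regression definitions: residual
standard deviation SDR = sqrt(SSE/(n−p)), R² = 1 − SSE/SST, and
R²adj = 1 − (1−R²)(n−1)/(n−p).  Confidence intervals are Wald intervals from
the asymptotic covariance sdr²·(JᵀJ)⁻¹ with Student-t quantiles on n−p
degrees of freedom; the half-time (t50/P50) interval is propagated by the
delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .core_io import TimeCourse
from .curves import ModelSpec, derived_half_time, get_model
from .errors import FitError

__all__ = [
    "LMOptions",
    "QualityMetrics",
    "FitResult",
    "initial_guess",
    "levenberg_marquardt",
    "fit_model",
    "fit_quality",
    "wald_ci",
]


@dataclass(frozen=True)
class LMOptions:
    """Tuning knobs for the Levenberg–Marquardt iteration.

    Defaults follow the classic Marquardt schedule: start with light damping
    (1e-3), divide by 10 on every accepted step, multiply by 10 on every
    rejected one.
    """

    damping_init: float = 1e-3
    damping_up: float = 10.0
    damping_down: float = 0.1
    max_iterations: int = 1000
    tol_sse_rel: float = 1e-10
    tol_grad: float = 1e-8
    jacobian_step_rel: float = 1e-6

    def __post_init__(self):
        if min(self.damping_init, self.tol_sse_rel, self.tol_grad, self.jacobian_step_rel) <= 0:
            raise ValueError("all LM tolerances must be positive")
        if not (0 < self.damping_down < 1 < self.damping_up):
            raise ValueError("need damping_down in (0,1) and damping_up > 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class QualityMetrics:
    """Goodness-of-fit summary on the response (percent) scale."""

    sse: float
    sst: float
    mse: float
    sdr: float
    r2: float
    r2_adj: float
    n_obs: int
    n_params: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FitResult:
    model: str
    params: object
    theta: np.ndarray
    covariance: np.ndarray
    quality: QualityMetrics
    half_time: float
    converged: bool
    n_iterations: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    half_time_ci: tuple[float, float] | None = None
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        spec = get_model(self.model)
        return {
            "model": self.model,
            "params": dict(zip(spec.param_names, self.theta.tolist())),
            "se": {
                name: float(math.sqrt(v)) if v >= 0 else None
                for name, v in zip(spec.param_names, np.diag(self.covariance))
            },
            "ci": {k: list(v) for k, v in self.ci.items()},
            "alpha": self.alpha,
            "sse": self.quality.sse,
            "sdr": self.quality.sdr,
            "r2": self.quality.r2,
            "r2_adj": self.quality.r2_adj,
            "t50_or_p50": self.half_time,
            "t50_or_p50_ci": list(self.half_time_ci) if self.half_time_ci else None,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "extra": self.extra,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Initialization heuristics
# ---------------------------------------------------------------------------


def _crossing_time(tc: TimeCourse, level_frac: float) -> float | None:
    """Interpolated time at which the percent curve crosses min + frac·span.

    Works for rising and declining courses; returns None when the level is
    never crossed (flat course).
    """
    t = tc.times
    y = tc.percent
    lo, hi = float(y.min()), float(y.max())
    if hi - lo <= 0:
        return None
    level = lo + level_frac * (hi - lo)
    for i in range(len(t) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return float(t[i] + (level - y0) * (t[i + 1] - t[i]) / (y1 - y0))
        if y0 == level:
            return float(t[i])
    return None


def initial_guess(model: str, tc: TimeCourse):
    """Data-driven starting parameters for a sigmoid fit.

    Asymptotes come from the observed extremes (the first observation for a
    declining longevity series), the half-time from the interpolated 50%
    level crossing (median observation time as fallback for flat data), and
    the width scale from the 16%–84% crossing spread (a quarter of the time
    range as fallback).
    """
    spec = get_model(model)
    if len(tc) < spec.n_params:
        raise FitError(
            f"{tc.label!r}: {len(tc)} points cannot identify {spec.n_params} parameters ({model})"
        )
    t = tc.times
    y = tc.percent
    vmin, vmax = float(y.min()), float(y.max())
    declining = y[-1] < y[0]
    t_range = float(t[-1] - t[0])

    t_half = _crossing_time(tc, 0.5)
    if t_half is None:
        t_half = float(np.median(t))
    t16, t84 = _crossing_time(tc, 0.16), _crossing_time(tc, 0.84)
    if t16 is not None and t84 is not None and abs(t84 - t16) > 0:
        width = abs(t84 - t16)
    else:
        width = t_range / 2.0 if t_range > 0 else 1.0

    span = max(vmax - vmin, 1e-6)
    if model == "boltzmann":
        # dt > 0 moves the curve from A1 to A2 as t grows, for either direction
        if declining:
            return spec.param_cls(A1=vmax, A2=vmin, t0=t_half, dt=width / 2.0)
        return spec.param_cls(A1=vmin, A2=vmax, t0=t_half, dt=width / 2.0)
    if model == "gompertz":
        return spec.param_cls(a=max(vmax, 1e-6), k=4.0 / width, tc=t_half)
    if model == "hill":
        return spec.param_cls(y0=vmin, a=span, b=4.0, c=max(t_half, 1e-6))
    if model == "logistic":
        if declining:
            return spec.param_cls(A=float(y[0]), t_half=t_half, s=width / 2.0)
        return spec.param_cls(A=vmax, t_half=t_half, s=-width / 2.0)
    raise KeyError(model)


# ---------------------------------------------------------------------------
# Core iteration
# ---------------------------------------------------------------------------


def _residuals(fn: Callable, theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Residuals y − f(θ, t), or None when θ is outside the model's domain."""
    try:
        pred = np.asarray(fn(theta, t), dtype=float)
    except (ValueError, FloatingPointError):
        return None
    if not np.all(np.isfinite(pred)):
        return None
    return y - pred


def _jacobian(fn, theta, t, y, r0, step_rel):
    """Forward-difference Jacobian of the residual vector in θ."""
    m, p = len(t), len(theta)
    J = np.empty((m, p))
    for k in range(p):
        h = step_rel * max(abs(theta[k]), 1.0)
        theta_h = theta.copy()
        theta_h[k] += h
        r_h = _residuals(fn, theta_h, t, y)
        if r_h is None:  # step out of domain: difference backwards instead
            theta_h[k] = theta[k] - h
            r_h = _residuals(fn, theta_h, t, y)
            if r_h is None:
                raise FitError(f"model not evaluable near theta={theta.tolist()}")
            h = -h
        J[:, k] = (r_h - r0) / h
    return -J  # d(prediction)/d(theta) convention: J = ∂f/∂θ


def _lm_core(fn, theta0, t, y, opts: LMOptions):
    theta = np.asarray(theta0, dtype=float).copy()
    r = _residuals(fn, theta, t, y)
    if r is None:
        raise FitError(f"initial parameters not evaluable: theta={theta.tolist()}")
    sse = float(r @ r)
    lam = opts.damping_init
    converged = False
    n_iter = 0
    J = None
    for n_iter in range(1, opts.max_iterations + 1):
        J = _jacobian(fn, theta, t, y, r, opts.jacobian_step_rel)
        g = J.T @ r  # gradient of ½SSE is −Jᵀr; use Jᵀr as the step RHS
        if np.max(np.abs(g)) < opts.tol_grad:
            converged = True
            break
        JtJ = J.T @ J
        accepted = False
        for _ in range(60):  # damping escalation
            A = JtJ + lam * np.diag(np.clip(np.diag(JtJ), 1e-300, None))
            try:
                delta = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                lam *= opts.damping_up
                continue
            r_new = _residuals(fn, theta + delta, t, y)
            if r_new is not None:
                sse_new = float(r_new @ r_new)
                if sse_new < sse:
                    rel_impr = (sse - sse_new) / max(sse, 1e-300)
                    theta = theta + delta
                    r, sse = r_new, sse_new
                    lam = max(lam * opts.damping_down, 1e-12)
                    accepted = True
                    if rel_impr < opts.tol_sse_rel:
                        converged = True
                    break
            lam *= opts.damping_up
        if not accepted:
            break  # damping exhausted: stuck (or at a non-smooth point)
        if converged:
            break
    # final Jacobian at the optimum for the covariance
    J = _jacobian(fn, theta, t, y, r, opts.jacobian_step_rel)
    return theta, sse, J, converged, n_iter


def fit_quality(observed, predicted, n_params: int) -> QualityMetrics:
    """SSE, SST, MSE, residual standard deviation, R² and adjusted R²."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    n = len(obs)
    if n <= n_params:
        raise ValueError(f"need n > n_params ({n} <= {n_params})")
    resid = obs - pred
    sse = float(resid @ resid)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    mse = sse / n
    sdr = math.sqrt(sse / (n - n_params))
    if sst > 0:
        r2 = 1.0 - sse / sst
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
    else:  # constant observations: R² undefined
        r2 = math.nan
        r2_adj = math.nan
    return QualityMetrics(
        sse=sse, sst=sst, mse=mse, sdr=sdr, r2=r2, r2_adj=r2_adj, n_obs=n, n_params=n_params
    )


def _covariance(J: np.ndarray, sdr: float) -> np.ndarray:
    JtJ = J.T @ J
    try:
        JtJ_inv = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        JtJ_inv = np.linalg.pinv(JtJ)
    cov = sdr**2 * JtJ_inv
    return (cov + cov.T) / 2.0  # symmetrize against round-off


def levenberg_marquardt(
    model: str | ModelSpec,
    tc: TimeCourse,
    init=None,
    opts: LMOptions | None = None,
    *,
    alpha: float = 0.05,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit a registered sigmoid model to a time course by damped least squares.

    The fit is unweighted least squares on the cumulative percent scale.
    ``init`` is a parameter dataclass (default: :func:`initial_guess`).  When
    the first run fails to converge, up to ``n_restarts`` restarts jitter the
    initial parameters by seed-controlled log-uniform factors in [0.5, 2] (a
    sign-preserving multiplicative jitter), keeping the best solution found.
    The returned SSE is never above the SSE of the initialization.
    """
    spec = get_model(model) if isinstance(model, str) else model
    opts = opts or LMOptions()
    if init is None:
        init = initial_guess(spec.name, tc)
    t = tc.times
    y = tc.percent
    if len(t) <= spec.n_params:
        raise FitError(
            f"{tc.label!r}: need more than {spec.n_params} points to fit {spec.name}"
        )

    theta0 = spec.to_array(init)
    theta, sse, J, converged, n_iter = _lm_core(spec, theta0, t, y, opts)

    if not converged and n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            factors = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=len(theta0)))
            trial0 = theta0 * factors
            try:
                theta_r, sse_r, J_r, conv_r, it_r = _lm_core(spec, trial0, t, y, opts)
            except FitError:
                continue
            if sse_r < sse:
                theta, sse, J, converged, n_iter = theta_r, sse_r, J_r, conv_r, it_r
            if converged:
                break

    params = spec.from_array(theta)
    quality = fit_quality(y, spec(theta, t), spec.n_params)
    cov = _covariance(J, quality.sdr)
    try:
        half_time = derived_half_time(spec.name, params)
    except FitError:
        half_time = math.nan
    result = FitResult(
        model=spec.name,
        params=params,
        theta=theta,
        covariance=cov,
        quality=quality,
        half_time=half_time,
        converged=converged,
        n_iterations=n_iter,
        alpha=alpha,
    )
    if spec.name == "gompertz":
        # tc is the inflection time (y = a/e there); the half-maximum time differs
        result.extra["inflection_time_tc"] = float(params.tc)
    wald_ci(result, alpha)
    return result


def wald_ci(fit: FitResult, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
    """Student-t Wald intervals per parameter, plus a delta-method half-time CI.

    Mutates ``fit.ci`` / ``fit.half_time_ci`` and returns the parameter
    intervals.  Noiseless fits have (numerically) zero covariance and yield
    degenerate intervals at the estimate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    spec = get_model(fit.model)
    q = fit.quality
    dof = q.n_obs - q.n_params
    if dof <= 0:
        raise FitError("no residual degrees of freedom for confidence intervals")
    if not np.all(np.isfinite(fit.covariance)):
        fit.warnings.append("non-finite covariance: confidence intervals omitted")
        fit.ci = {}
        fit.half_time_ci = None
        return fit.ci
    tcrit = float(stats.t.ppf(1 - alpha / 2, dof))
    ci: dict[str, tuple[float, float]] = {}
    for name, est, var in zip(spec.param_names, fit.theta, np.diag(fit.covariance)):
        hw = tcrit * math.sqrt(max(var, 0.0))
        ci[name] = (float(est - hw), float(est + hw))
    fit.ci = ci
    fit.alpha = alpha

    # delta method for the derived half-time
    if math.isfinite(fit.half_time):
        grad = np.zeros(len(fit.theta))
        for k in range(len(fit.theta)):
            h = 1e-6 * max(abs(fit.theta[k]), 1.0)
            for sign_h in (h, -h):  # prefer central, fall back to one-sided
                try:
                    tp = fit.theta.copy()
                    tp[k] += sign_h
                    tm = fit.theta.copy()
                    tm[k] -= sign_h
                    f_p = derived_half_time(fit.model, spec.from_array(tp))
                    f_m = derived_half_time(fit.model, spec.from_array(tm))
                    grad[k] = (f_p - f_m) / (2 * sign_h)
                    break
                except (ValueError, FitError):
                    continue
        var_ht = float(grad @ fit.covariance @ grad)
        hw = tcrit * math.sqrt(max(var_ht, 0.0))
        fit.half_time_ci = (fit.half_time - hw, fit.half_time + hw)
    else:
        fit.half_time_ci = None
    return ci


def fit_model(
    model: str,
    tc: TimeCourse,
    *,
    opts: LMOptions | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> FitResult:
    """Convenience wrapper: initial guess + LM fit + quality + Wald CIs."""
    return levenberg_marquardt(model, tc, None, opts, alpha=alpha, seed=seed)
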