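"""Sigmoid model functions for germination and longevity time courses.

Four classical forms, all returning cumulative percentages:

* Boltzmann   y = (A1 − A2) / (1 + exp((t − t0)/dt)) + A2
* Gompertz    y = a · exp(−exp(−k (t − tc)))
* Hill        y = y0 + a x^b / (c^b + x^b),  x ≥ 0
* logistic    y = A / (1 + exp((t − t_half)/s))

The logistic scale ``s`` is sign-coded: s > 0 gives a declining curve (the
longevity use case, viability falling over storage time), s < 0 a rising
germination curve.  Every evaluator clamps its exponent to ±700 before
exponentiation so extreme arguments saturate at the plateaus instead of
overflowing.

``derived_half_time`` returns the time at which the curve crosses the lower
plateau plus half the plateau span — the fitted t50 (germination) or P50
(longevity).  For Boltzmann, Hill and the logistic this is a parameter
(t0, c, t_half); for Gompertz it is tc − ln(ln 2)/k, since y(tc) = a/e, not
a/2 (tc itself is also worth reporting, as the inflection time).
"""

from __future__ import annotations

import math
from dataclasses import astuple, dataclass, fields
from typing import Callable

import numpy as np

from .errors import FitError

EXP_CLAMP = 700.0  # exp(709) is the float64 overflow edge

__all__ = [
    "BoltzmannParams",
    "GompertzParams",
    "HillParams",
    "LogisticParams",
    "eval_boltzmann",
    "eval_gompertz",
    "eval_hill",
    "eval_logistic",
    "derived_half_time",
    "plateaus",
    "ModelSpec",
    "MODELS",
    "get_model",
]


def _safe_exp(z):
    return np.exp(np.clip(z, -EXP_CLAMP, EXP_CLAMP))


@dataclass(frozen=True)
class BoltzmannParams:
    """A1: initial plateau (%); A2: final plateau (%); t0: half-transition time; dt: time constant (≠ 0)."""

    A1: float
    A2: float
    t0: float
    dt: float

    def __post_init__(self):
        if self.dt == 0:
            raise ValueError("Boltzmann dt must be nonzero")


@dataclass(frozen=True)
class GompertzParams:
    """a: asymptote (%) > 0; k: rate (1/time) > 0; tc: inflection time."""

    a: float
    k: float
    tc: float

    def __post_init__(self):
        if self.a <= 0 or self.k <= 0:
            raise ValueError("Gompertz requires a > 0 and k > 0")


@dataclass(frozen=True)
class HillParams:
    """y0: intercept (%); a: span above y0 (%); b: shape > 0; c: half-response time > 0."""

    y0: float
    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.b <= 0 or self.c <= 0:
            raise ValueError("Hill requires b > 0 and c > 0")


@dataclass(frozen=True)
class LogisticParams:
    """A: plateau (%); t_half: half-transition time; s: scale (s > 0 declining, s < 0 rising)."""

    A: float
    t_half: float
    s: float

    def __post_init__(self):
        if self.s == 0:
            raise ValueError("logistic scale s must be nonzero")


def eval_boltzmann(p: BoltzmannParams, t):
    t = np.asarray(t, dtype=float)
    y = (p.A1 - p.A2) / (1.0 + _safe_exp((t - p.t0) / p.dt)) + p.A2
    return y if y.ndim else float(y)


def eval_gompertz(p: GompertzParams, t):
    t = np.asarray(t, dtype=float)
    y = p.a * _safe_exp(-_safe_exp(-p.k * (t - p.tc)))
    return y if y.ndim else float(y)


def eval_hill(p: HillParams, x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill model is defined for x >= 0 only")
    # work in log space: x^b overflows for b·log(x) large
    with np.errstate(divide="ignore"):
        log_ratio = p.b * (np.log(x) - math.log(p.c))  # log((x/c)^b); -inf at x=0
    frac = 1.0 / (1.0 + _safe_exp(-log_ratio))  # x^b / (c^b + x^b)
    y = p.y0 + p.a * frac
    return y if y.ndim else float(y)


def eval_logistic(p: LogisticParams, t):
    t = np.asarray(t, dtype=float)
    y = p.A / (1.0 + _safe_exp((t - p.t_half) / p.s))
    return y if y.ndim else float(y)


def plateaus(model: str, params) -> tuple[float, float]:
    """(lower plateau, upper plateau) of the curve's asymptotic span."""
    if model == "boltzmann":
        lo, hi = sorted((params.A1, params.A2))
    elif model == "gompertz":
        lo, hi = 0.0, params.a
    elif model == "hill":
        lo, hi = params.y0, params.y0 + params.a
    elif model == "logistic":
        lo, hi = sorted((0.0, params.A))
    else:
        raise KeyError(f"unknown model {model!r}")
    return float(lo), float(hi)


def derived_half_time(model: str, params) -> float:
    """Time at which the curve crosses lower plateau + span/2 (t50 / P50)."""
    lo, hi = plateaus(model, params)
    if hi - lo <= 0:
        raise FitError(f"{model}: degenerate plateau span, half-time undefined")
    if model == "boltzmann":
        return float(params.t0)
    if model == "hill":
        return float(params.c)
    if model == "gompertz":
        return float(params.tc - math.log(math.log(2.0)) / params.k)
    if model == "logistic":
        return float(params.t_half)
    raise KeyError(f"unknown model {model!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: parameter container, vectorized evaluator, array packing."""

    name: str
    param_cls: type
    eval_fn: Callable
    param_names: tuple[str, ...]
    positive: tuple[str, ...]  # parameters that must stay strictly positive

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_array(self, params) -> np.ndarray:
        return np.array(astuple(params), dtype=float)

    def from_array(self, theta: np.ndarray):
        return self.param_cls(*map(float, theta))

    def __call__(self, theta: np.ndarray, t):
        return self.eval_fn(self.param_cls(*map(float, theta)), t)


MODELS: dict[str, ModelSpec] = {
    "boltzmann": ModelSpec(
        "boltzmann", BoltzmannParams, eval_boltzmann, ("A1", "A2", "t0", "dt"), ()
    ),
    "gompertz": ModelSpec("gompertz", GompertzParams, eval_gompertz, ("a", "k", "tc"), ("a", "k")),
    "hill": ModelSpec("hill", HillParams, eval_hill, ("y0", "a", "b", "c"), ("b", "c")),
    "logistic": ModelSpec("logistic", LogisticParams, eval_logistic, ("A", "t_half", "s"), ()),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None
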