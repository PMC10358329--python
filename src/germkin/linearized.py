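"""Linearized probit/logit viability models and the KS normality check.

Seed survival curves (germination percentage versus storage time) are
classically analysed by transforming the observed proportions with a probit
(inverse standard-normal CDF) or logit (log-odds) link and fitting a straight
line in time by ordinary least squares:

    F(p_i) = beta0 + beta1 * t_i

The half-viability storage time is the zero crossing of the transformed line,
P50 = -beta0 / beta1, since F(0.5) = 0 under both links.  Proportions of
exactly 0 or 1 are undefined under either link; they are excluded by default
or, when counts are available, shrunk by the standard empirical-probit
adjustment (n*p + 0.5)/(n + 1).

This is the textbook linearized fit, not a binomial GLM with iteratively
reweighted least squares; quality metrics are therefore reported on the
transformed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .core_io import TimeCourse
from .errors import FitError
from .fitting import QualityMetrics, fit_quality

Link = Literal["probit", "logit"]
Boundary = Literal["exclude", "adjust"]

__all__ = [
    "probit_transform",
    "logit_transform",
    "inverse_link",
    "LinearFit",
    "fit_linearized",
    "ks_normality",
]


def _check_open_unit(p: np.ndarray) -> None:
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("proportion must lie strictly in (0, 1); handle boundaries upstream")


def probit_transform(p):
    """Probit link: standard normal quantile of a proportion in (0, 1)."""
    p = np.asarray(p, dtype=float)
    _check_open_unit(np.atleast_1d(p))
    z = stats.norm.ppf(p)
    return z if z.ndim else float(z)


def logit_transform(p):
    """Logit link: ln(p / (1 − p)) for a proportion in (0, 1)."""
    p = np.asarray(p, dtype=float)
    _check_open_unit(np.atleast_1d(p))
    z = np.log(p / (1.0 - p))
    return z if z.ndim else float(z)


def inverse_link(link: Link, z):
    """Map a transformed value back to a proportion (normal CDF / expit)."""
    z = np.asarray(z, dtype=float)
    if link == "probit":
        p = stats.norm.cdf(z)
    elif link == "logit":
        from scipy.special import expit

        p = expit(z)
    else:
        raise ValueError(f"unknown link {link!r}")
    return p if p.ndim else float(p)


_TRANSFORMS = {"probit": probit_transform, "logit": logit_transform}


@dataclass
class LinearFit:
    """Result of an OLS fit of link(p) on time."""

    link: Link
    beta0: float
    beta1: float
    covariance: np.ndarray  # 2x2, order (beta0, beta1)
    half_time: float  # P50 (or t50): time where the fitted proportion is 0.5
    quality: QualityMetrics  # on the transformed scale
    excluded_points: list[tuple[float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def predict_proportion(self, t):
        return inverse_link(self.link, self.beta0 + self.beta1 * np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "p50": self.half_time,
            "r2": self.quality.r2,
            "sdr": self.quality.sdr,
            "excluded_points": [list(pt) for pt in self.excluded_points],
            "warnings": self.warnings,
        }


def fit_linearized(tc: TimeCourse, link: Link = "probit", boundary: Boundary = "exclude") -> LinearFit:
    """OLS straight-line fit of the link-transformed proportions on time.

    ``boundary='exclude'`` drops observations with p in {0, 1} (they are
    recorded in ``excluded_points``); ``boundary='adjust'`` replaces every p
    by (n·p + 0.5)/(n + 1), which requires count-valued data.  The
    half-viability time is −beta0/beta1.
    """
    if link not in _TRANSFORMS:
        raise ValueError(f"unknown link {link!r}")
    t = tc.times.astype(float)
    p = tc.proportions
    excluded: list[tuple[float, float]] = []
    if boundary == "adjust":
        if tc.value_kind != "counts" or tc.n_seeds is None:
            raise FitError("boundary='adjust' requires count-valued data with n_seeds")
        n = tc.n_seeds
        p = (n * p + 0.5) / (n + 1)
    elif boundary == "exclude":
        keep = (p > 0) & (p < 1)
        excluded = [(float(ti), float(pi)) for ti, pi in zip(t[~keep], p[~keep])]
        t, p = t[keep], p[keep]
    else:
        raise ValueError(f"unknown boundary policy {boundary!r}")
    if len(t) < 2:
        raise FitError(
            f"{tc.label!r}: need at least 2 usable points for a linearized fit, have {len(t)}"
        )

    z = _TRANSFORMS[link](p)
    import statsmodels.api as sm

    X = sm.add_constant(t)
    ols = sm.OLS(z, X).fit()
    beta0, beta1 = map(float, ols.params)
    cov = np.asarray(ols.cov_params(), dtype=float)
    if len(t) > 2:
        quality = fit_quality(z, ols.fittedvalues, n_params=2)
    else:  # exactly determined line: zero residual, no residual dof
        sst = float(np.sum((z - z.mean()) ** 2))
        quality = QualityMetrics(
            sse=0.0, sst=sst, mse=0.0, sdr=math.nan,
            r2=1.0 if sst > 0 else math.nan,
            r2_adj=math.nan, n_obs=2, n_params=2,
        )

    warnings: list[str] = []
    if beta1 == 0:
        half_time = math.nan
        warnings.append("zero slope: half-viability time undefined")
    else:
        half_time = -beta0 / beta1
    return LinearFit(
        link=link,
        beta0=beta0,
        beta1=beta1,
        covariance=cov,
        half_time=half_time,
        quality=quality,
        excluded_points=excluded,
        warnings=warnings,
    )


def ks_normality(sample, alpha: float = 0.05) -> tuple[float, bool]:
    """One-sample Kolmogorov–Smirnov normality check with fitted mean/sd.

    D = sup |F̂_n(x) − Φ((x − mean)/sd)| over the empirical steps; the null
    is rejected when D exceeds the asymptotic critical value
    c(alpha)/sqrt(n) with c(alpha) = sqrt(−ln(alpha/2)/2) (the plain-KS
    approximation, anticonservative when parameters are estimated — the
    Lilliefors correction is deliberately not applied).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need at least 5 observations, have {len(x)}")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance sample: normality check undefined")
    d_stat = float(stats.kstest(x, "norm", args=(float(x.mean()), sd)).statistic)
    critical = math.sqrt(-0.5 * math.log(alpha / 2.0)) / math.sqrt(len(x))
    return d_stat, d_stat > critical
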