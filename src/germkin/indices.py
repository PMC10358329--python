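"""Nonparametric germination kinetics indices.

Computed per repetition from a cumulative time course:

* germinability ``G`` — final cumulative percentage,
* mean germination time ``t_mean`` — event-weighted mean of interval end
  times (new germinations are attributed to the scoring time that closed
  the interval, matching daily-scoring practice),
* mean germination rate ``v_mean = 1 / t_mean``,
* interpolated level-crossing times ``t10``, ``t16``, ``t50``, ``t84``,
* uniformity ``u_8416 = t84 - t16``,
* trapezoidal area under the cumulative-percent curve up to a cutoff
  (120 h by default), reported both raw (percent·time) and normalized by
  the cutoff so a lot at 100% from t=0 scores 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_io import ExperimentSet, TimeCourse
from .errors import UndefinedIndexError, ValidationError

Baseline = Literal["of_final", "of_sample"]
Pooling = Literal["mean_of_repetitions", "pooled_counts"]

AUC_DEFAULT_CUTOFF = 120.0

__all__ = [
    "germinability",
    "mean_germination_time",
    "mean_germination_rate",
    "time_to_fraction",
    "uniformity_u8416",
    "auc",
    "IndexReport",
    "index_report",
]


def germinability(tc: TimeCourse) -> float:
    """Final cumulative value as a percentage of seeds sown (G)."""
    return float(tc.percent[-1])


def mean_germination_time(tc: TimeCourse) -> float:
    """Event-weighted mean time  t̄ = Σ nᵢtᵢ / Σ nᵢ.

    nᵢ are the new germinations in the interval ending at tᵢ (first
    differences of the cumulative values, the value at the first scoring
    time counting in full).  Undefined when nothing germinated.
    """
    increments = np.diff(tc.values, prepend=0.0)
    total = increments.sum()
    if total <= 0:
        raise UndefinedIndexError("mean germination time undefined: no germination events")
    return float(np.dot(increments, tc.times) / total)


def mean_germination_rate(tc: TimeCourse) -> float:
    """Mean germination rate  v̄ = 1 / t̄  (inverse time units)."""
    return 1.0 / mean_germination_time(tc)


def time_to_fraction(tc: TimeCourse, q: float, baseline: Baseline = "of_final") -> float:
    """Time at which the cumulative curve reaches fraction ``q`` of a baseline.

    ``of_final`` targets q of the final cumulative value (e.g. t50 = median
    germination time of the germinated seeds); ``of_sample`` targets q of the
    seeds sown (or of 100% for percent-valued courses).  The crossing time is
    linearly interpolated between the bracketing observations; when the level
    coincides with an observed value on a plateau, the earliest time attaining
    it is returned.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    values = tc.values
    final = float(values[-1])
    if baseline == "of_final":
        level = q * final
    elif baseline == "of_sample":
        total = tc.n_seeds if tc.value_kind == "counts" else 100.0
        level = q * total
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if level > final:
        raise UndefinedIndexError(
            f"{tc.label!r}: level {level:g} never reached (maximum attained {final:g})",
            attained=final,
        )
    j = int(np.searchsorted(values, level, side="left"))
    if values[j] == level:
        return float(tc.times[j])
    if j == 0:  # level below the first observation: attained by the first scoring
        return float(tc.times[0])
    i = j - 1
    t_i, t_j = tc.times[i], tc.times[j]
    c_i, c_j = values[i], values[j]
    return float(t_i + (level - c_i) * (t_j - t_i) / (c_j - c_i))


def uniformity_u8416(tc: TimeCourse) -> float:
    """Germination uniformity  u_8416 = t84 − t16  (smaller is more uniform)."""
    return time_to_fraction(tc, 0.84, "of_final") - time_to_fraction(tc, 0.16, "of_final")


def auc(tc: TimeCourse, cutoff: float = AUC_DEFAULT_CUTOFF) -> tuple[float, float]:
    """Trapezoidal area under the cumulative-percent curve on [0, cutoff].

    The origin (0, 0) is prepended when the first scoring time is positive;
    past the last observation the curve is held flat; a curve extending past
    the cutoff is interpolated at the cutoff.  Returns
    ``(raw area in percent·time, area / cutoff in percent)``.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    t = tc.times
    y = tc.percent
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
    if t[-1] < cutoff:
        t = np.concatenate([t, [cutoff]])
        y = np.concatenate([y, [y[-1]]])
    elif t[-1] > cutoff:
        y_cut = float(np.interp(cutoff, t, y))
        keep = t < cutoff
        t = np.concatenate([t[keep], [cutoff]])
        y = np.concatenate([y[keep], [y_cut]])
    raw = float(np.trapezoid(y, t))
    return raw, raw / cutoff


_INDEX_FIELDS = ("G", "t_mean", "v_mean", "t50", "t10", "t16", "t84", "u_8416", "auc", "auc_normalized")


def _course_indices(tc: TimeCourse, t10_baseline: Baseline, cutoff: float) -> dict[str, float]:
    out: dict[str, float] = {"label": tc.label, "G": germinability(tc)}

    def _try(fn, *args):
        try:
            return fn(*args)
        except UndefinedIndexError:
            return math.nan

    out["t_mean"] = _try(mean_germination_time, tc)
    out["v_mean"] = 1.0 / out["t_mean"] if out["t_mean"] == out["t_mean"] else math.nan
    out["t50"] = _try(time_to_fraction, tc, 0.5, "of_final")
    out["t10"] = _try(time_to_fraction, tc, 0.1, t10_baseline)
    out["t16"] = _try(time_to_fraction, tc, 0.16, "of_final")
    out["t84"] = _try(time_to_fraction, tc, 0.84, "of_final")
    out["u_8416"] = out["t84"] - out["t16"]
    out["auc"], out["auc_normalized"] = auc(tc, cutoff)
    return out


@dataclass
class IndexReport:
    """Pooled kinetics indices plus the per-repetition breakdown."""

    G: float
    t_mean: float
    v_mean: float
    t50: float
    t10: float
    t16: float
    t84: float
    u_8416: float
    auc: float
    auc_normalized: float
    pooling: Pooling
    per_repetition: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            **{k: getattr(self, k) for k in _INDEX_FIELDS},
            "pooling": self.pooling,
            "per_repetition": self.per_repetition,
        }


def index_report(
    experiment: ExperimentSet,
    pooling: Pooling = "mean_of_repetitions",
    *,
    t10_baseline: Baseline = "of_final",
    cutoff: float = AUC_DEFAULT_CUTOFF,
) -> IndexReport:
    """Kinetics indices per repetition plus a pooled summary.

    ``mean_of_repetitions`` averages each index over repetitions (undefined
    repetitions are skipped per index); ``pooled_counts`` sums counts across
    repetitions on a common time grid first and computes the indices once on
    the merged course.
    """
    kinds = {c.value_kind for c in experiment.courses}
    if len(kinds) > 1:
        raise ValidationError("mixed counts/percent repetitions cannot be pooled")
    per_rep = [_course_indices(c, t10_baseline, cutoff) for c in experiment.courses]

    if pooling == "mean_of_repetitions":
        pooled = {}
        for key in _INDEX_FIELDS:
            vals = [r[key] for r in per_rep if r[key] == r[key]]  # drop NaN
            pooled[key] = float(np.mean(vals)) if vals else math.nan
    elif pooling == "pooled_counts":
        if kinds != {"counts"}:
            raise ValidationError("pooled_counts pooling requires count-valued repetitions")
        grids = {tuple(c.times.tolist()) for c in experiment.courses}
        if len(grids) > 1:
            raise ValidationError("pooled_counts requires a common time grid across repetitions")
        merged = TimeCourse(
            label="pooled",
            times=experiment.courses[0].times.copy(),
            values=np.sum([c.values for c in experiment.courses], axis=0),
            value_kind="counts",
            n_seeds=sum(c.n_seeds for c in experiment.courses),
        )
        pooled = _course_indices(merged, t10_baseline, cutoff)
        pooled.pop("label")
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    return IndexReport(pooling=pooling, per_repetition=per_rep, **pooled)
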