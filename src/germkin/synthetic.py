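"""Seeded simulation of replicated germination and longevity experiments.

The generator emulates the standard seed-lab design: a few replicates of
``n_seeds`` seeds each (four replicates of 50 is the classic layout), scored
at fixed times against a latent sigmoid.  For germination-type data the
latent curve gives the cumulative germination probability at each scoring
time and binomial noise is drawn as a counting process: the increment over
each interval is binomial in the seeds that have not yet germinated, with
the conditional hazard (p_i − p_{i−1})/(1 − p_{i−1}).  This guarantees
monotone non-decreasing counts bounded by n_seeds, i.e. each seed germinates
at most once.

Longevity-type data are independent germination assays at each storage time:
counts at different times come from separate seed lots, so they are drawn as
independent binomials and legitimately decline over time.

Ground truth (parameters and the analytic half-time) is returned alongside
the data so recovery tests and sensitivity studies can score themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_io import ExperimentSet, TimeCourse
from .curves import derived_half_time, get_model
from .errors import GermkinError

Noise = Literal["none", "binomial"]
Kind = Literal["germination", "longevity"]

__all__ = ["SimConfig", "latent_percent", "simulate_course", "simulate_experiment"]

_CLIP_TOL = 1e-6


@dataclass
class SimConfig:
    """Ground truth and design for one simulated experiment."""

    model: str
    params: object
    times: Sequence[float]
    n_seeds: int = 50
    n_reps: int = 4
    noise: Noise = "binomial"
    rng_seed: int = 0
    kind: Kind = "germination"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise GermkinError("times must be a strictly increasing grid with >= 2 points")
        if self.n_seeds < 1 or self.n_reps < 1:
            raise GermkinError("n_seeds and n_reps must be >= 1")
        get_model(self.model)  # validate the name early


def latent_percent(cfg: SimConfig) -> np.ndarray:
    """Latent cumulative percentage at each scoring time, clipped to [0, 100]."""
    spec = get_model(cfg.model)
    y = np.asarray(spec.eval_fn(cfg.params, cfg.times), dtype=float)
    if np.any(y < -100 * _CLIP_TOL) or np.any(y > 100 * (1 + _CLIP_TOL)):
        raise GermkinError(
            f"latent model emits percentages outside [0, 100]: range [{y.min():g}, {y.max():g}]"
        )
    return np.clip(y, 0.0, 100.0)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_course(cfg: SimConfig, rep_index: int = 0) -> TimeCourse:
    """One repetition of the configured design, deterministic under (rng_seed, rep_index)."""
    p = latent_percent(cfg) / 100.0
    rng = np.random.default_rng([cfg.rng_seed, rep_index])
    n = cfg.n_seeds
    if cfg.noise == "none":
        counts = _round_half_up(n * p)
        if cfg.kind == "germination":
            counts = np.maximum.accumulate(counts)
    elif cfg.noise == "binomial":
        if cfg.kind == "germination":
            counts = np.empty(len(p))
            germinated = 0
            p_prev = 0.0
            for i, p_i in enumerate(p):
                if p_prev >= 1.0:
                    hazard = 0.0
                else:
                    hazard = min(max((p_i - p_prev) / (1.0 - p_prev), 0.0), 1.0)
                germinated += rng.binomial(n - germinated, hazard)
                counts[i] = germinated
                p_prev = p_i
        else:  # independent assays per storage time
            counts = rng.binomial(n, p).astype(float)
    else:
        raise GermkinError(f"unknown noise kind {cfg.noise!r}")
    return TimeCourse(
        label=f"Rep {rep_index + 1}",
        times=cfg.times.copy(),
        values=counts,
        value_kind="counts",
        n_seeds=n,
    )


def simulate_experiment(cfg: SimConfig) -> tuple[ExperimentSet, dict]:
    """All repetitions plus a ground-truth record.

    The ground truth carries the generating model, its parameters and the
    analytic half-time (t50 for germination, P50 for longevity) so a
    downstream fit can be scored without re-deriving anything.
    """
    courses = [simulate_course(cfg, i) for i in range(cfg.n_reps)]
    spec = get_model(cfg.model)
    try:
        half_time = derived_half_time(cfg.model, cfg.params)
    except GermkinError:
        half_time = math.nan
    truth = {
        "model": cfg.model,
        "params": dict(zip(spec.param_names, spec.to_array(cfg.params).tolist())),
        "half_time": half_time,
        "kind": cfg.kind,
        "n_seeds": cfg.n_seeds,
        "n_reps": cfg.n_reps,
        "noise": cfg.noise,
        "rng_seed": cfg.rng_seed,
        "times": cfg.times.tolist(),
    }
    return ExperimentSet(name=f"simulated-{cfg.model}", courses=courses, module=cfg.kind), truth
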