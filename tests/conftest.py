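import numpy as np
import pytest

from germkin import ExperimentSet, TimeCourse


@pytest.fixture
def fixture_course() -> TimeCourse:
    """The hand-checked reference course: 50 seeds scored at 24 h steps."""
    return TimeCourse(
        label="Protrusion 1",
        times=[24, 48, 72, 96, 120],
        values=[0, 10, 30, 45, 45],
        value_kind="counts",
        n_seeds=50,
    )


@pytest.fixture
def fixture_experiment(fixture_course) -> ExperimentSet:
    rep2 = TimeCourse(
        label="Protrusion 2",
        times=fixture_course.times.copy(),
        values=fixture_course.values.copy(),
        value_kind="counts",
        n_seeds=50,
    )
    return ExperimentSet(name="fixture", courses=[fixture_course, rep2])


@pytest.fixture
def dense_hill_course():
    """A percent-valued course sampled densely from a known Hill curve."""
    from germkin import HillParams
    from germkin.curves import eval_hill

    t = np.linspace(1, 200, 60)
    y = eval_hill(HillParams(0, 90, 4, 63), t)
    return TimeCourse("dense", t, y, "percent")
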