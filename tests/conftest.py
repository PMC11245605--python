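import numpy as np
import pytest

from srtkit.simulate import SimulationConfig, simulate_object_in_context
from srtkit.trial_data import ExplorationRecord


@pytest.fixture(scope="session")
def object_cohort():
    """One seeded 10-animal object-in-context cohort (context-novel, delta 0.6)."""
    return simulate_object_in_context(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trial(trial_type="test_in_second", t1=4.0, t2=1.0, trial=1,
               animal="m01", sides=("left", "right")):
    """Hand-built single trial: stimulus 'x' from exposure1, 'y' from exposure2.

    t1/t2 are the test durations of x and y respectively.
    """
    base = dict(experiment_id="e", animal_id=animal, sex="male", session=1,
                trial=trial, stimulus_kind="object")
    recs = []
    for phase, sid in (("exposure1", "x"), ("exposure2", "y")):
        for side in ("left", "right"):
            recs.append(ExplorationRecord(
                phase=phase, trial_type="not_applicable", stimulus_id=sid,
                side=side, duration=5.0, **base))
    recs.append(ExplorationRecord(phase="test", trial_type=trial_type,
                                  stimulus_id="x", side=sides[0], duration=t1, **base))
    recs.append(ExplorationRecord(phase="test", trial_type=trial_type,
                                  stimulus_id="y", side=sides[1], duration=t2, **base))
    return recs
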