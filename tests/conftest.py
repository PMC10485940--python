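import logging

import numpy as np
import pytest

import lifetab as lt

# the variance warnings about count-free extended ages are expected noise here
logging.getLogger("lifetab").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scenario():
    return lt.default_scenario()


@pytest.fixture(scope="session")
def reference_schedule(scenario):
    """Large-exposure reference schedule (deterministic under the scenario seed)."""
    return lt.simulate_schedule(scenario, "reference")


@pytest.fixture(scope="session")
def reference_results(reference_schedule):
    return lt.LifeTableModel(reference_schedule).fit()


@pytest.fixture(scope="session")
def standard_results(scenario):
    """Fitted table for the pooled elevated-mortality group (the 'standard')."""
    return lt.LifeTableModel(lt.simulate_schedule(scenario, "disabled")).fit()


def make_schedule(mx, ages=None, exposure=1e9, group_id="g", sex="male"):
    """Deterministic schedule with deaths = exposure * mx (negligible noise)."""
    mx = np.asarray(mx, dtype=float)
    if ages is None:
        ages = np.arange(len(mx))
    expo = np.full(mx.shape, float(exposure))
    return lt.MortalitySchedule(
        group_id=group_id, sex=sex, ages=np.asarray(ages, dtype=int),
        exposure=expo, deaths=expo * mx,
    )


@pytest.fixture
def deterministic_schedule():
    return make_schedule
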