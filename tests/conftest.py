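import numpy as np
import pytest

from stresscircuit import (
    CircuitParameters,
    InductionSchedule,
    STANDARD_VARIANTS,
    SolverSettings,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return CircuitParameters()


@pytest.fixture(scope="session")
def schedule():
    return InductionSchedule(iptg_conc=1.0, t_induce=2.0, t_end=12.0)


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def variant_trajectories(params, schedule, settings):
    """All four standard variants simulated once for the whole session."""
    return {label: simulate(params, v, schedule, settings) for label, v in STANDARD_VARIANTS.items()}


@pytest.fixture(scope="session")
def sampling_times(schedule):
    return np.arange(0.0, schedule.t_end + 1e-9, 0.5)
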