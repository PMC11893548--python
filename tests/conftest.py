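import numpy as np
import pytest

import affectdyn as ad

#: Published single-case transition probabilities (rows A-D), two decimals.
AN_VALUES = np.array(
    [
        [0.23, 0.22, 0.26, 0.28],
        [0.23, 0.24, 0.21, 0.32],
        [0.13, 0.58, 0.13, 0.15],
        [0.15, 0.24, 0.42, 0.19],
    ]
)


@pytest.fixture(scope="session")
def an_matrix() -> ad.TransitionMatrix:
    return ad.example_patient_matrix()


@pytest.fixture(scope="session")
def schedule() -> ad.BlockSchedule:
    return ad.generate_schedule(seed=7)


@pytest.fixture(scope="session")
def windows(schedule) -> ad.WindowSet:
    return ad.place_windows(schedule)


@pytest.fixture(scope="session")
def uniform_profile() -> ad.VariabilityProfile:
    return ad.VariabilityProfile.uniform(30.0)


@pytest.fixture(scope="session")
def simulated_rr(schedule, windows, uniform_profile) -> ad.RRSeries:
    return ad.simulate_rr(
        schedule, windows, uniform_profile, ad.SimulationConfig(seed=42)
    )
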