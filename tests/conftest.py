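import pytest

from fragsurv import (
    SimulationConfig,
    encode_predictors,
    expand_to_person_period,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_trials():
    """A small but structurally complete simulated dataset (4 participants)."""
    cfg = SimulationConfig(
        n_controls=3, include_patient=True, n_objects=40, n_manmade=20, seed=123
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_pp(small_trials):
    return expand_to_person_period(encode_predictors(small_trials))
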