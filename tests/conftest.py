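import numpy as np
import pytest
from hypothesis import settings

import lungscreen as ls
from lungscreen.parameters import ModelParameters, UncertainParameter

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ls.default_parameters()


@pytest.fixture(scope="session")
def values(params) -> dict:
    return params.base_values()


@pytest.fixture(scope="session")
def life_table():
    return ls.make_life_table()


@pytest.fixture(scope="session")
def baseline():
    return ls.make_baseline_distribution()


@pytest.fixture(scope="session")
def flat_life_table():
    """Constant-hazard life table (q = 0.25/yr) for closed-form oracles."""
    ages = np.arange(40, 101)
    q = np.full(len(ages), 0.25)
    return ls.LifeTable(ages=ages, q_male=q, q_female=q)


@pytest.fixture(scope="session")
def reference_outcomes():
    return ls.load_reference_outcomes()


def point_mass_parameters(params: ModelParameters) -> ModelParameters:
    """Every parameter collapsed to a point mass at its base value."""
    return ModelParameters(
        {
            n: UncertainParameter(n, p.base, p.base, p.base, "fixed")
            for n, p in params.params.items()
        }
    )
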