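import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout_perm():
    from echogaze import default_layout
    return default_layout("permeable")


@pytest.fixture(scope="session")
def layout_refl():
    from echogaze import default_layout
    return default_layout("reflective")


@pytest.fixture(scope="session")
def permeable_cohort():
    """One seeded 7-bat permeable cohort (flights 1 and 12), shared
    across tests that only read from it."""
    from echogaze.simulate import SimulationConfig, simulate_cohort
    rng = np.random.default_rng(2024)
    return simulate_cohort(SimulationConfig(condition="permeable"), rng)


@pytest.fixture(scope="session")
def permeable_counts(permeable_cohort):
    from echogaze.kinematics import count_by_type
    pulses = pd.concat([f.pulses for f in permeable_cohort], ignore_index=True)
    cohorts = pd.DataFrame([
        {"bat_id": f.bat_id, "condition": f.condition,
         "flight_number": f.flight_number} for f in permeable_cohort])
    return count_by_type(pulses, cohorts=cohorts)


@pytest.fixture(scope="session")
def glmm_design():
    """Balanced 7-bat x 2-flight design frame for model tests."""
    return pd.DataFrame({
        "bat_id": np.repeat([f"b{i}" for i in range(7)], 2),
        "flight_number": np.tile([1, 12], 7),
        "y": 0,
    })
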