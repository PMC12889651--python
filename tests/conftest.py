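import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctmd.metad import Hill, HillList, ThermoParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def thermo() -> ThermoParams:
    return ThermoParams(beta=1.0, gamma=10.0, temperature=300.0)


def random_hill_list(
    rng: np.random.Generator,
    n_hills: int,
    thermo: ThermoParams,
    s_range=(0.3, 2.4),
    max_height: float = 1.5,
    sigma_range=(0.05, 0.2),
) -> HillList:
    """Random, time-ordered hill list for property tests."""
    times = np.sort(rng.uniform(0.0, 100.0, n_hills))
    centers = rng.uniform(*s_range, n_hills)
    sigmas = rng.uniform(*sigma_range, n_hills)
    heights = rng.uniform(0.0, max_height, n_hills)
    return HillList.from_arrays(times, centers, sigmas, heights, thermo)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
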