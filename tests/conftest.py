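import numpy as np
import pytest

from nh3iam import default_params, generate_region, total_inventory
from nh3iam.params import EmissionFactors, RegionConfig, scaled_region


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def factors(params):
    return EmissionFactors.from_dict(params["emission_factors"])


@pytest.fixture(scope="session")
def small_region(params):
    """A 12x12 region for fast unit tests; national totals as configured."""
    block = scaled_region(params["region"], 12, 12, n_provinces=9)
    return generate_region(RegionConfig.from_dict(block), seed=7)


@pytest.fixture(scope="session")
def small_baseline(small_region, factors):
    return total_inventory(small_region, factors)


@pytest.fixture(scope="session")
def default_region(params):
    """The shipped default study region (36x36, seed 42)."""
    return generate_region(RegionConfig.from_dict(params["region"]), seed=42)


@pytest.fixture(scope="session")
def default_baseline(default_region, factors):
    return total_inventory(default_region, factors)


@pytest.fixture(scope="session")
def default_scenarios(default_region, default_baseline, factors, params):
    from nh3iam import build_all_scenarios
    return build_all_scenarios(default_region, default_baseline, factors, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
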