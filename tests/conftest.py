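import numpy as np
import pytest

import plantresp as pr


@pytest.fixture(scope="session")
def pfts():
    return pr.load_default_pfts()


@pytest.fixture(scope="session")
def broadleaf(pfts):
    return pfts["broadleaf_tree"]


@pytest.fixture(scope="session")
def small_world():
    """Seeded 8x8 global domain with one year of daily forcing."""
    domain = pr.make_grid(pr.GridConfig(n_lat=8, n_lon=8))
    climate = pr.generate_climate(domain, pr.ClimateScenario(n_days=365), seed=11)
    veg = pr.generate_vegetation(domain, seed=11, climate=climate)
    return domain, climate, veg


@pytest.fixture(scope="session")
def small_result(small_world):
    domain, climate, veg = small_world
    return pr.run_factorial(domain, climate, veg)
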