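import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clamtrace as ct

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def korea_specs():
    return ct.builtin_fixtures("korea_table1")


@pytest.fixture(scope="session")
def korea_frame(korea_specs):
    """102 synthetic Korean clams with bulk-isotope features, seed 0."""
    return ct.samples_to_frame(ct.generate_samples(korea_specs, seed=0))


@pytest.fixture(scope="session")
def merged_specs():
    """17 Korean sites with isotope, FA-composition and δ13C-FA blocks."""
    lists = [
        ct.builtin_fixtures(n)
        for n in ("korea_table1", "fa_profiles_synthetic", "csia_table4")
    ]
    return ct.merge_specs(lists[0], *lists[1:])


@pytest.fixture(scope="session")
def merged_frame(merged_specs):
    return ct.samples_to_frame(ct.generate_samples(merged_specs, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
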