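import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paleobeta.occurrences import SiteAssemblage, TimeBinConfig, assign_time_bins
from paleobeta.simulate import GeneratorConfig, bin_dataset, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_site(site_id, species, lon=-100.0, lat=40.0, age=12_000.0, modern=False):
    return SiteAssemblage(
        site_id=site_id,
        lon=lon,
        lat=lat,
        age_bp=None if modern else age,
        modern=modern,
        species=frozenset(species),
    )


@pytest.fixture
def toy_sites():
    return [
        make_site("s1", {"x", "y"}),
        make_site("s2", {"y", "z"}),
        make_site("s3", {"x", "y", "z"}),
    ]


@pytest.fixture(scope="session")
def small_cfg():
    """Compact 7-bin generator settings used across test modules."""
    return GeneratorConfig(
        n_species=120,
        n_sites_per_bin=(12,) * 7,
        range_radius_log_mean=math.log(1500.0),
        extinction_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg, 123)


@pytest.fixture(scope="session")
def small_binned(small_cfg, small_dataset):
    return bin_dataset(small_dataset, small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
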