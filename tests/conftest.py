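import numpy as np
import pytest

from fusegan.config import desk_profile
from fusegan.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """A minimal but structurally complete cohort configuration."""
    return SyntheticConfig(
        volume_size=16,
        n_paired_per_class=3,
        n_unpaired_per_class=1,
        noise_sd=0.05,
        effect_size=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def desk_cfg():
    return desk_profile(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
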