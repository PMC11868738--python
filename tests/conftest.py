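import numpy as np
import pytest

from nestpattern.synthetic import (
    LandscapeConfig,
    NestProcessConfig,
    ThomasConfig,
    generate_dataset,
    make_landscape,
)


@pytest.fixture(scope="session")
def landscape():
    """Default-size synthetic band with 8 leks over 5 years."""
    return make_landscape(LandscapeConfig(seed=1))


@pytest.fixture(scope="session")
def small_landscape():
    """Small 2-year landscape for fast model tests."""
    cfg = LandscapeConfig(width=1200.0, height=600.0, n_leks=4,
                          years=(2018, 2019), leks_by_year={2018: 3, 2019: 4},
                          seed=2)
    return make_landscape(cfg)


@pytest.fixture(scope="session")
def clustered_dataset():
    """Thomas-clustered, lek-attracted nests at the five seasonal counts."""
    return generate_dataset(
        LandscapeConfig(seed=1),
        NestProcessConfig(beta_lek=-0.01, clustering=ThomasConfig(8, 30.0), seed=2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
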