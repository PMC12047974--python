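import numpy as np
import pytest

from fcgrad.scheme import make_parcel_scheme


@pytest.fixture(scope="session")
def scheme100():
    return make_parcel_scheme(100, 7, seed=0)


@pytest.fixture(scope="session")
def scheme14():
    return make_parcel_scheme(14, 7, seed=1)


@pytest.fixture(scope="session")
def null_cohort20():
    """20-subject, 100-parcel cohort with no planted effects and no site effects."""
    from fcgrad.simulate import CohortConfig, SiteEffect, synthesize_cohort

    cfg = CohortConfig(
        n_parcels=100,
        group_sizes={"HC": 12, "ROP": 8, "ROD": 0, "CHR-P": 0},
        site_effects={"site_A": SiteEffect(), "site_B": SiteEffect()},
        seed=0,
    )
    return synthesize_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
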