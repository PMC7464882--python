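import numpy as np
import pytest

from cndiag import (
    GeneratorConfig,
    NutrientProfile,
    Specimen,
    close_composition,
    clr_transform,
    load_fixtures,
)
from cndiag.synthetic import profile_from_composition, sample_compositions


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def site1(fixtures):
    return fixtures.site1


@pytest.fixture(scope="session")
def site2(fixtures):
    return fixtures.site2


@pytest.fixture(scope="session")
def site1_comp(site1):
    return close_composition(site1)


@pytest.fixture(scope="session")
def site2_comp(site2):
    return close_composition(site2)


@pytest.fixture(scope="session")
def norms(fixtures):
    return fixtures.norms


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_compositions(n, seed):
    """Logistic-normal draws at the packaged norms, for property tests."""
    return sample_compositions(GeneratorConfig(n=n, seed=seed))


@pytest.fixture(scope="session")
def specimen_factory():
    """Build minimal specimens from closed compositions."""

    def make(compositions, age=1.0, dbh=5.5, prefix="T"):
        return [
            Specimen(
                id=f"{prefix}{i:04d}",
                profile=profile_from_composition(c),
                clone="C0",
                age_yr=age,
                dbh_cm=dbh,
            )
            for i, c in enumerate(compositions)
        ]

    return make
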