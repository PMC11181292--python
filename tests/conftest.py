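import pandas as pd
import pytest

from ucclaims.catalog import default_catalog
from ucclaims.cohort import build_cohort
from ucclaims.simulate import GeneratorConfig, generate_claims


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def bundle(catalog):
    """A mid-sized synthetic claims bundle shared across tests."""
    return generate_claims(GeneratorConfig(n_patients=2000, seed=7), catalog)


@pytest.fixture(scope="session")
def cohort_result(bundle, catalog):
    """(cohort, episodes, tally) built from the shared bundle."""
    return build_cohort(bundle, catalog)


def day(n: int, origin: str = "2018-01-01") -> pd.Timestamp:
    """Day-offset helper used by hand-built tables."""
    return pd.Timestamp(origin) + pd.Timedelta(days=n)
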