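import numpy as np
import pytest
from hypothesis import settings

from oncoclone.simdata import SimConfig, simulate_patient

settings.register_profile("no_db", database=None)
settings.load_profile("no_db")


@pytest.fixture(scope="session")
def default_patient():
    """One deterministic patient at the default study conditions."""
    return simulate_patient(SimConfig(seed=42), patient_id="FIX_001")


@pytest.fixture(scope="session")
def deep_patient():
    """Higher-depth patient for tree/topology tests."""
    return simulate_patient(SimConfig(mean_depth=500, seed=42), patient_id="FIX_500")


@pytest.fixture(scope="session")
def toy_spectrum():
    from oncoclone.dnds import build_site_spectrum, toy_cds

    return build_site_spectrum(toy_cds())


@pytest.fixture(scope="session")
def signature_reference():
    from oncoclone.signatures import synthetic_signature_matrix

    return synthetic_signature_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
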