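import numpy as np
import pytest

from eegdays.core import HeadModel
from eegdays.decompose import extended_infomax
from eegdays.dipoles import fit_decomposition
from eegdays.preprocess import clean
from eegdays.synth import fast_scenario, simulate_session, standard_montage_30


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def montage30(head):
    return standard_montage_30(head)


@pytest.fixture(scope="session")
def scenario():
    return fast_scenario(seed=11)


@pytest.fixture(scope="session")
def session_pair(scenario):
    """One simulated session + ground truth (8 sources, 30 channels, 250 Hz)."""
    return simulate_session(scenario, 0, 0)


@pytest.fixture(scope="session")
def cleaned_session(session_pair):
    rec, _ = session_pair
    cleaned, report = clean(rec)
    return cleaned, report


@pytest.fixture(scope="session")
def session_dec(cleaned_session):
    """Full 30-component extended-infomax decomposition of the cleaned session."""
    cleaned, _ = cleaned_session
    return extended_infomax(cleaned.data, seed=7)


@pytest.fixture(scope="session")
def session_fits(session_dec, montage30, head):
    return fit_decomposition(session_dec, montage30, head)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
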