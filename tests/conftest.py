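import numpy as np
import pytest

from brainmeth.readcall import CallerConfig, _AssayAligner
from brainmeth.simulate import default_assay_panel, default_profiles


@pytest.fixture(scope="session")
def panel():
    """The four synthetic assay archetypes (two hypo, two hyper)."""
    return default_assay_panel()


@pytest.fixture(scope="session")
def hypo_assay(panel):
    return panel[0]


@pytest.fixture(scope="session")
def hyper_assay(panel):
    return panel[2]


@pytest.fixture(scope="session")
def caller_config():
    return CallerConfig()


@pytest.fixture(scope="session")
def engines(panel, caller_config):
    """Cached aligners, one per assay, shared across the whole run."""
    return {a.name: _AssayAligner(a, caller_config) for a in panel}


@pytest.fixture(scope="session")
def profiles(panel):
    """assay name -> (brain profile, decoy profile)."""
    return {a.name: default_profiles(a) for a in panel}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
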