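import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dcapskit.enzymes import default_catalogue, filter_enzymes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# a small, motif-diverse sub-catalogue (degenerate and concrete sites,
# 4-10 nt, palindromic and not) used wherever the full 232-enzyme snapshot
# would only add runtime
SUB20 = [
    "AflII", "ApoI", "AvaI", "BamHI", "BsaBI", "BsrGI", "ClaI", "DdeI",
    "DraI", "EcoRI", "EcoRV", "HaeIII", "HindIII", "HinfI", "KpnI", "NdeI",
    "NlaIII", "NsiI", "PstI", "SpeI",
]


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def sub20(catalogue):
    subset = filter_enzymes(catalogue, include=SUB20)
    assert len(subset) == 20
    return subset


@pytest.fixture
def rng():
    return np.random.default_rng(20170915)
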