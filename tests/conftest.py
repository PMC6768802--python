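import numpy as np
import pytest

from diastolefit.constitutive import GuccioneParams
from diastolefit.forward_model import UnloadedGeometry
from diastolefit.insilico import generate_insilico_case


@pytest.fixture(scope="session")
def default_geometry():
    return UnloadedGeometry()


@pytest.fixture(scope="session")
def healthy_params():
    """Four-parameter set at the healthy-myocardium magnitude."""
    return GuccioneParams(c1=1.0, c2=19.13, c3=10.67, c4=12.76)


@pytest.fixture(scope="session")
def default_case():
    """Noiseless six-frame synthetic diastole (shared; generation is fast)."""
    return generate_insilico_case()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
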