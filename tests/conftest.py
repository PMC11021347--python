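import numpy as np
import pytest

from glucoclamp.model_core import ClampProtocol, GIGParameters, GIParameters


@pytest.fixture
def gi_params():
    """Physiologic GI anchor parameters (T2DM-like fasting state)."""
    return GIParameters(k1=0.07, k2=5e-3, k3=0.05, k4=2.2e-4, k5=1.25,
                        k6=4.0, k7=0.15, k8=1e-3)


@pytest.fixture
def gig_params():
    """Physiologic GIG anchor parameters."""
    return GIGParameters(k1=0.07, k2=5e-3, k3=0.05, k4=2.2e-4, k5=2.5e-3,
                         k6=4.0, k7=0.15, k8=1e-3, kGN=3.5e-4, kGgS=900.0,
                         kGgC=0.12, kratio=0.5, kCPC=0.025)


@pytest.fixture
def zero_protocol():
    return ClampProtocol.zero(duration=120.0, body_weight=65.0)


@pytest.fixture
def infused_protocol():
    n = 121
    return ClampProtocol(120.0, np.full(n, 2.0), np.full(n, 1.25), 5.2,
                         65.0, 48.75)
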