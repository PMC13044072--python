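import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import geobands as gb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_scheme():
    """Full-precision geometric scheme with the canonical anchor and ratio."""
    return gb.build_scheme()


@pytest.fixture(scope="session")
def paper_scheme():
    """Scheme under the tabulated-rounding protocol (2-dp centers)."""
    return gb.build_scheme(rounding="paper")


@pytest.fixture(scope="session")
def traditional_scheme():
    return gb.traditional_scheme()


@pytest.fixture()
def alpha_peak_psd():
    """Synthetic PSD: 1/f background with one alpha peak at 10.2 Hz."""
    spec = gb.SynthSpec(
        background_amp=20.0,
        background_exp=1.0,
        peaks=((10.2, 15.0, 1.0),),
        noise_sd=0.0,
        grid=(1.0, 45.0, 221),
        seed=7,
    )
    return gb.synth_psd(spec)


@pytest.fixture()
def flat_psd():
    """Constant density 1 over 1-40 Hz on a fine grid."""
    freqs = np.linspace(1.0, 40.0, 391)
    return gb.PSDTable(freqs=freqs, power=np.ones_like(freqs))
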