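import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ligaquant.spectra import wavenumber_axis, collagen_like_peaks, build_spectrum
from ligaquant.synth import (
    MieDistortionParams,
    PhantomSpecFTIR,
    PhantomSpecQPLM,
    generate_ftir_phantom,
    generate_qplm_phantom,
)


@pytest.fixture(scope="session")
def axis():
    return wavenumber_axis()


@pytest.fixture(scope="session")
def collagen_spectrum(axis):
    return build_spectrum(collagen_like_peaks(), axis=axis)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, distortion-free FTIR phantom (tissue = exact group
    spectrum everywhere on the mask)."""
    spec = PhantomSpecFTIR(
        grid=(24, 24), noise_sd=0.0, area_jitter_sd=0.0, mie=None, seed=1
    )
    return generate_ftir_phantom(spec, group="control")


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpecFTIR(
        grid=(32, 32),
        noise_sd=0.005,
        area_jitter_sd=0.05,
        mie=MieDistortionParams(mixing_weight=0.3),
        seed=2,
    )
    return generate_ftir_phantom(spec, group="ACLT")


@pytest.fixture(scope="session")
def ideal_qplm():
    """Noiseless triangular-wave orientation phantom."""
    spec = PhantomSpecQPLM(
        grid=(200, 520),
        crimp_angle_true=10.0,
        crimp_length_true=100.0,
        orientation_noise_sd=0.0,
        seed=3,
    )
    return generate_qplm_phantom(spec)
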