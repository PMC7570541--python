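import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lactospec as ls

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def main37_plan():
    return ls.build_sample_plan("main37")


@pytest.fixture(scope="session")
def nir_library():
    return ls.build_band_library("nir")


@pytest.fixture(scope="session")
def nir_set_default(main37_plan, nir_library):
    """37-sample NIR set at documented default noise, fixed seed."""
    instrument = ls.default_instrument("nir", seed=1)
    return ls.generate_spectra(main37_plan, nir_library, instrument)


@pytest.fixture(scope="session")
def nir_set_noiseless(main37_plan, nir_library):
    instrument = ls.default_instrument("nir", seed=1).scaled(0.0)
    return ls.generate_spectra(main37_plan, nir_library, instrument)


@pytest.fixture()
def toy_set():
    """Tiny 3-sample set on a short uniform axis for I/O round trips."""
    axis = np.arange(100.0, 110.0)
    rng = np.random.default_rng(7)
    return ls.SpectraSet(
        axis=axis,
        samples=rng.normal(size=(3, axis.size)),
        concentrations=[0.0, 1.5, 3.0],
        region="uvvis",
    )
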