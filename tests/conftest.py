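import pytest

from kdrcall import default_panel, make_barcodes
from kdrcall.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def barcode():
    return make_barcodes(1, seed=7)[0]


@pytest.fixture
def cfg():
    return GeneratorConfig()


@pytest.fixture
def quiet_cfg():
    """Noiseless generator settings for deterministic melt-curve checks."""
    return GeneratorConfig(tm_noise_sd=0.0, height_jitter=0.0, baseline_noise_sd=0.0)
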