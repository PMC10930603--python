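import warnings

import numpy as np
import pytest

from cerequant.synthgen import SynthConfig


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    """Keep expected generator/fit warnings out of the test log."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def small_invivo_config() -> SynthConfig:
    """Desk-size in-vivo stack: 96x96 px field, 40 z-planes, 12 timepoints."""
    return SynthConfig(
        image_shape=(96, 96),
        zstack_depth_um=40,
        noise_sd=5.0,
        drift_px=1,
        bleed_alpha=0.15,
        process_turnover=0.1,
        seed=2,
    )


@pytest.fixture
def clean_invivo_config(small_invivo_config) -> SynthConfig:
    """Same geometry with noise, drift, and bleed disabled."""
    return small_invivo_config.replace(noise_sd=0.0, drift_px=0, bleed_alpha=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
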