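import numpy as np
import pytest

from gliderpam import PRESETS, PipelineConfig, SpectrogramConfig, make_click_train

FS = 194_000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def det_spec_cfg():
    return SpectrogramConfig.detection(FS)


@pytest.fixture(scope="session")
def unknown_train():
    """One seeded 11-click unknown-beaked-whale train at SNR 15 dB."""
    wave, truth = make_click_train(
        PRESETS["unknown_bw"], n_clicks=11, duration_s=2.2, sample_rate=FS,
        seed=7, snr_db=15.0,
    )
    return wave, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
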