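import numpy as np
import pytest

from perisacc import SynthConfig, gen_trialset


@pytest.fixture(scope="session")
def highsnr_session():
    """Small high-SNR synthetic session shared by recovery-style tests."""
    cfg = SynthConfig(trials_per_direction=8, n_channels=2, snr=5.0, seed=11)
    ts, truth = gen_trialset(cfg)
    return cfg, ts, truth


@pytest.fixture(scope="session")
def null_session():
    """Null-mode session (snr = 0): noise only, events metadata intact."""
    cfg = SynthConfig(trials_per_direction=8, n_channels=2, snr=0.0, seed=12)
    ts, truth = gen_trialset(cfg)
    return cfg, ts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
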