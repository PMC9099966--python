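import numpy as np
import pytest

from soilfusion import SynthConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy paired dataset shared by read-only tests."""
    cfg = SynthConfig(
        n_samples=60, n_mir_channels=120, n_xrf_channels=160, n_latents=6,
        complementarity=0.5, seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise- and artifact-free dataset: attributes exactly linear in latents."""
    cfg = SynthConfig(
        n_samples=50, n_mir_channels=100, n_xrf_channels=140, n_latents=6,
        complementarity=0.0, noise_sd=0.0, scatter_sd=0.0, n_xrf_latents=0,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
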