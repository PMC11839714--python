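import numpy as np
import pytest

from mtintegrity import ScoringProtocol, SyntheticParams


@pytest.fixture
def default_params() -> SyntheticParams:
    """The packaged (calibrated) generator defaults."""
    return SyntheticParams()


@pytest.fixture
def clean_params() -> SyntheticParams:
    """Noise-free, void-free, texture-free render for deterministic checks."""
    return SyntheticParams(noise_model="gaussian", noise_sd=0.0,
                           n_plastids=0, texture_sd=0.0)


@pytest.fixture
def small_params() -> SyntheticParams:
    """A fast 64x64 render for I/O and pipeline plumbing tests."""
    return SyntheticParams(image_height=64, image_width=64, n_filaments=19,
                           n_plastids=40)


@pytest.fixture
def protocol() -> ScoringProtocol:
    return ScoringProtocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
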