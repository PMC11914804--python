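"""Shared fixtures: small parameter sets that keep unit tests fast."""

import numpy as np
import pytest

from duroclust import ModelParams


@pytest.fixture
def tiny_params() -> ModelParams:
    """Coarse-grid parameters for fast bookkeeping tests."""
    return ModelParams(Nc=6, dx=0.25, T_end=1.0, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
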