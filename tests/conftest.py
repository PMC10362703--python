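import numpy as np
import pytest

from rlcausal import (Dataset, EncoderConfig, GroundTruthSEM, normalize,
                      sample_linear_sem)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_encoder():
    """Reduced network for fast tests: 2 layers, width 16."""
    return EncoderConfig(n_layers=2, d_model=16, n_heads=4, d_ff=32, n_s=32)


@pytest.fixture
def chain3_data():
    """Normalized m=500 sample from the chain X1 -> X2 -> X3 with strong
    linear effects and unit noise."""
    rng = np.random.default_rng(2024)
    dag = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8)
    weights = dag * 1.5
    sem = GroundTruthSEM(dag, weights, 1.0)
    return normalize(sample_linear_sem(sem, 500, rng))


@pytest.fixture
def gauss_data():
    """Independent-noise 4-variable dataset (no true edges)."""
    rng = np.random.default_rng(7)
    return Dataset(rng.normal(size=(300, 4)))
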