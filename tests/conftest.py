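import numpy as np
import pytest

from dtifusion.head_train import ModelConfig
from dtifusion.synthetic_data import SynthSpec, generate_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_config():
    """Minimal model for fast unit tests (float64 for tight tolerances)."""
    return ModelConfig(
        epochs=1, d_model=16, n_heads=2, n_bert_layers=1, n_gat_layers=1,
        att_pool_layers=1, itm_layers=1, ntn_k=4, mlp_hidden=16,
        batch_size=8, seed=11, dtype="float64", dropout=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """64 noiseless pairs with short proteins; planted signal intact."""
    spec = SynthSpec(n_pairs=64, noise_rate=0.0, seed=5, protein_length=(30, 60))
    records, provenance = generate_pairs(spec)
    return records, provenance
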