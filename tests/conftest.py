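import numpy as np
import pytest

from scsem.data import CountMatrix
from scsem.network import ModelConfig
from scsem.simulate import SimConfig, simulate_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = np.array(
        [
            [1, 4, 0, 3],
            [4, 16, 2, 0],
            [2, 8, 1, 1],
        ]
    )
    return CountMatrix(counts, ["c0", "c1", "c2"], ["g0", "g1", "g2", "g3"])


@pytest.fixture(scope="session")
def small_sim():
    """Two well-separated groups, small enough for fast training tests."""
    return simulate_counts(
        SimConfig(
            n_cells=120, n_genes=300, n_groups=2, n_batches=2,
            de_prob=0.4, de_logfc_loc=1.5, de_logfc_sd=0.3,
            dropout_rate=0.05, seed=7,
        )
    )


def fast_model_config(**overrides) -> ModelConfig:
    defaults = dict(
        encoder_widths=[64, 16, 8],
        pretrain_epochs=40,
        finetune_epochs=25,
        seed=0,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)
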