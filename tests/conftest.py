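import numpy as np
import pytest

from scdfn import TrainConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy3_sim():
    """The well-separated 3-cluster fixture used across the suite."""
    return simulate.fixture("easy3")


@pytest.fixture(scope="session")
def small_sim():
    """A small strongly separated dataset for fast training tests."""
    cfg = simulate.SimConfig(
        n_cells=80, n_genes=100, k_clusters=3,
        de_fraction=0.3, logfc_scale=2.0, seed=7,
    )
    return simulate.simulate(cfg)


def fast_config(**overrides) -> TrainConfig:
    """A down-sized training configuration for unit tests."""
    kwargs = dict(
        latent_dim=10, ae_hidden=(64, 32), igae_hidden=(64,), zinb_hidden=32,
        epochs_pretrain=5, epochs_joint=3, epochs_finetune=8,
        min_epochs_finetune=4, p_update_interval=2,
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
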