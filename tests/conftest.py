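import numpy as np
import pytest
from hypothesis import settings

from coupletrans import PipelineConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from coupletrans.synthetic_data import SyntheticConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200-gene paired dataset with default planted structure."""
    cfg = SyntheticConfig(n_genes=200, seed=1)
    return cfg, *generate_paired_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """All-null paired dataset (no planted effects)."""
    cfg = SyntheticConfig(n_genes=300, frac_coupled=0.0, frac_uncoupled=0.0,
                          frac_null=1.0, frac_motif_genes=0.0, seed=2)
    return cfg, *generate_paired_dataset(cfg)


@pytest.fixture()
def fast_config():
    return PipelineConfig(n_boot=50, n_perm=100, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
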