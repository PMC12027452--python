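import numpy as np
import pytest

from iadep import (
    ModelConfig,
    TraitConfig,
    compute_priors,
    embed_matrix,
    simulate_genotypes,
    simulate_trait,
)


@pytest.fixture(scope="session")
def small_panel():
    """200 samples x 300 markers, no missing data."""
    return simulate_genotypes(200, 300, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    cfg = TraitConfig(n_qtl_additive=20, h2_target=0.6, seed=12)
    pheno, truth = simulate_trait(small_panel, cfg)
    return pheno, truth


@pytest.fixture(scope="session")
def small_priors(small_panel, small_trait):
    pheno, _ = small_trait
    return compute_priors(small_panel, pheno)


@pytest.fixture(scope="session")
def small_embedded(small_panel, small_priors):
    return embed_matrix(small_panel, small_priors)


@pytest.fixture
def tiny_model_config():
    """Network config small enough for second-scale training in tests."""
    return ModelConfig(
        conv_width=8,
        n_heads=2,
        stem_stride=4,
        block_strides=(2, 2),
        global_hidden=16,
        n_global_tokens=2,
        mlp_hidden=(16, 8),
        epochs=8,
        batch_size=64,
        seed=0,
    )
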