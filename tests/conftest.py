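import numpy as np
import pytest

from pansubnet import (
    BagSimConfig,
    ExpressionSimConfig,
    PanSubNetConfig,
    init_params,
    simulate_expression_cohort,
    simulate_slide_bags,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_config():
    """Small dims so forward/backward passes are cheap."""
    return PanSubNetConfig(D_p=6, D_c=4, attn_dim=4, fused_dim=8, mil_hidden=5, seed=0)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_params(tiny_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_bags(tiny_config):
    return simulate_slide_bags(BagSimConfig(
        n_slides=4, patches_per_slide=(2, 3), cells_per_patch=(2, 5),
        D_p=tiny_config.D_p, D_c=tiny_config.D_c, seed=11,
    ))


@pytest.fixture(scope="session")
def expression_cohort():
    cfg = ExpressionSimConfig(n_classical=40, n_basal=40, n_intermediate=20, seed=5)
    return simulate_expression_cohort(cfg)
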