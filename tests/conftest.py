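import numpy as np
import pytest

from skaresnet.backbone import NetSpec, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Desk-scale SKA network: 4 blocks, 1/8 widths, 64-px input."""
    return NetSpec(variant="ska", stage_blocks=(1, 1, 1, 1), num_classes=4,
                   input_size=64, width_divisor=8)


@pytest.fixture
def tiny_model(tiny_spec):
    return build_model(tiny_spec, rng=np.random.default_rng(0))


def randomize_bn_stats(module, rng):
    """Give every batch-norm nontrivial running statistics so eval-mode
    oracles exercise the normalization."""
    from skaresnet.layers import BatchNorm1d, BatchNorm2d

    for m in module.modules():
        if isinstance(m, (BatchNorm1d, BatchNorm2d)):
            m.running_mean = rng.normal(0.0, 0.5, m.num_features)
            m.running_var = rng.uniform(0.5, 2.0, m.num_features)
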