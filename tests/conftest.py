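import numpy as np
import pytest

from rcunet.architectures import (BackboneConfig, DenseUnitSpec, ResPathSpec,
                                  UNetModel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_backbone():
    """Smallest config that still exercises all four pooling levels."""
    return BackboneConfig(input_extent=(16, 16),
                          encoder_filters=(4, 8, 16, 32, 64))


@pytest.fixture
def tiny_rcunet(tiny_backbone):
    respaths = [ResPathSpec(level=i + 1, n_units=4 - i,
                            unit_channels=tiny_backbone.encoder_filters[i])
                for i in range(4)]
    dense = DenseUnitSpec(base_filters=4, growth_rate=1, stages=4)
    return UNetModel(tiny_backbone, respaths, dense)
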