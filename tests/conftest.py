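import numpy as np
import pytest

from tsdnet.attention import DirectionalWeights


def random_weights(rng: np.random.Generator, shape) -> DirectionalWeights:
    """A valid directional-weight triple with entries in [0, 1]."""
    return DirectionalWeights(
        a_h=rng.uniform(size=shape),
        a_v=rng.uniform(size=shape),
        a_d=rng.uniform(size=shape),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model():
    from tsdnet import build_model, small_config

    cfg = small_config(n_classes=3, seed=7, image_size=16,
                       backbone_widths=(4, 8), d_fuse=16)
    return build_model(cfg)
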