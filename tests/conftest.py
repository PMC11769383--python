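import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_model():
    from afnnet import ModelConfig, build_afn_net

    return build_afn_net(ModelConfig.tiny(seed=7))


def random_mask(rng, h=16, w=16, p=0.4):
    return (rng.random((h, w)) < p).astype(np.uint8)
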