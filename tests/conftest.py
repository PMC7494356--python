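import numpy as np
import pytest

from graytex import TextureGroup

# frequently used second-order groups (G=3)
H_SUM = TextureGroup(3, (1, 1, 0, 0))    # horizontal sum
H_DIFF = TextureGroup(3, (1, 2, 0, 0))   # horizontal difference
V_SUM = TextureGroup(3, (1, 0, 1, 0))    # vertical sum
D_DIFF = TextureGroup(3, (1, 0, 0, 2))   # main-diagonal difference
A_DIFF = TextureGroup(3, (0, 1, 2, 0))   # anti-diagonal difference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
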