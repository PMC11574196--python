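import logging

import numpy as np
import pytest

# generator warnings about fully-segregated frames are expected noise in tests
logging.getLogger("mitohet").setLevel(logging.ERROR)
logging.getLogger("mitohet.quantify").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
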