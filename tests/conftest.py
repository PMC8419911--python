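import numpy as np
import pytest

from concatcall.synthdata import melanoma_like_panel, random_panel


@pytest.fixture(scope="session")
def small_panel():
    """Four random ~260 nt amplicons, E=1000, with a junction adapter."""
    return random_panel(n_amplicons=4, seed=1)


@pytest.fixture(scope="session")
def mel_panel():
    """Synthetic 15-amplicon panel with 384 assessed loci."""
    return melanoma_like_panel(seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
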