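import numpy as np
import pytest

from mammoread import radiomics


@pytest.fixture(scope="session")
def rfs_bank():
    return radiomics.build_rfs_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def textured_patch():
    from mammoread.synthetic import generate_texture_patch

    return generate_texture_patch(64, 3.0, 2.0, 30.0, seed=7)


def random_quantized(rng, size=6, levels=4):
    """Small random integer image for brute-force texture oracles."""
    return rng.integers(0, levels, size=(size, size)).astype(np.int64)
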