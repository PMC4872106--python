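import numpy as np
import pytest

from ocrevolve import canonical_scaffold, make_named_fixtures


@pytest.fixture(scope="session")
def scaffold():
    """The packaged synthetic Ocr scaffold (116 aa, 34 chargeable)."""
    return canonical_scaffold()


@pytest.fixture(scope="session")
def fixtures(scaffold):
    return make_named_fixtures(scaffold)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
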