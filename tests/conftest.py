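from __future__ import annotations

import numpy as np
import pytest

from emr_pheno_sens import load_lexicon, load_weights


@pytest.fixture(scope="session")
def weights():
    return load_weights()


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
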