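import numpy as np
import pytest

from acimage.cochleogram import build_filterbank
from acimage.stimuli import synthesize_targets


@pytest.fixture(scope="session")
def targets():
    return synthesize_targets()


@pytest.fixture(scope="session")
def filterbank():
    return build_filterbank()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
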