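import logging

import numpy as np
import pytest

from histossl import generate_cohort
from histossl.preprocess import PreprocessConfig
from histossl.trainer import PatchImageCache

logging.getLogger("histossl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """16 slides (8 positive), deterministic; shared across the session."""
    return generate_cohort(16, 0.5, seed=3)


@pytest.fixture(scope="session")
def small_patches(small_cohort):
    return [p for s in small_cohort for p in s.patches]


@pytest.fixture(scope="session")
def shared_cache():
    """One working-resolution image cache so patches render once per session."""
    return PatchImageCache(PreprocessConfig(target_size=16))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
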