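import dataclasses

import numpy as np
import pytest

from cryocount.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small, fast phantom: 12 clusters in a 6x128x128 volume."""
    return PhantomConfig(image_shape=(6, 128, 128), n_clusters=12, seed=9)


@pytest.fixture
def clean_config(small_config):
    """Noise-free, background-free, singleton-only variant."""
    return dataclasses.replace(
        small_config, cluster_size_pmf={1: 1.0}, intensity_cv=0.0,
        noise_sd=0.0, background_level=0.0, bleed_fraction=0.0)
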