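import numpy as np
import pytest

from gradnorm.atlas import make_atlas
from gradnorm.simulate import SimTruth


@pytest.fixture(scope="session")
def tiny_atlas():
    """21 parcels, 3 per network."""
    return make_atlas(21, network_sizes={n: 3 for n in (
        "Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
        "Limbic", "Control", "DMN")})


@pytest.fixture(scope="session")
def atlas100():
    return make_atlas(100)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free, heterogeneity-free generator: planted structure only."""
    return SimTruth(seed=7, noise_sd=0.0, hub_edge_frac=0.0,
                    module_jitter=0.0, grad_jitter=0.0)
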