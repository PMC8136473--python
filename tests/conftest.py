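import numpy as np
import pytest
from hypothesis import settings

import abtomo as ab

# property tests run derandomised so the suite is reproducible everywhere
settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: 25 well-separated fibres plus sub-size distractors.

    Lengths are drawn tightly around 19 µm so every fibre's aspect ratio
    clears the default filter; small bright specks are present but fall
    below the minimum size, and there are no large distractors or noise.
    """
    spec = ab.PhantomSpec(
        shape=(192, 192, 192),
        n_fibres=25,
        length_mu_log=np.log(19.0),
        length_sigma_log=0.12,
        noise_sd=0.0,
        n_voids=1,
        n_small_distractors=15,
        n_large_distractors=0,
        seed=42,
    )
    volume, records = ab.generate_phantom(spec)
    return spec, volume, records


@pytest.fixture(scope="session")
def default_phantom():
    """Default study-condition phantom (256³, 100 fibres, noise 0.05)."""
    spec = ab.PhantomSpec(seed=11)
    volume, records = ab.generate_phantom(spec)
    return spec, volume, records


@pytest.fixture(scope="session")
def stitch_phantom():
    """Tall noisy phantom whose fibres cross the 5-chunk slab boundaries."""
    spec = ab.PhantomSpec(
        shape=(350, 96, 96),
        n_fibres=30,
        length_mu_log=np.log(18.0),
        length_sigma_log=0.18,
        n_voids=0,
        n_large_distractors=0,
        seed=21,
    )
    volume, records = ab.generate_phantom(spec)
    return spec, volume, records
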