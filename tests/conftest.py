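import numpy as np
import pytest

from uresnet.phantom import PhantomConfig, generate_phantom
from uresnet.volume_io import compute_brain_mask, normalize_intensity


@pytest.fixture(scope="session")
def phantom_case():
    """One default synthetic case (raw volume + labels)."""
    return generate_phantom(PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_case(phantom_case):
    """The same case, brain-masked and intensity-normalized."""
    vol, labels = phantom_case
    from dataclasses import replace

    vol = replace(vol, intensities=vol.intensities.copy())
    vol.brain_mask = compute_brain_mask(vol)
    return normalize_intensity(vol), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
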