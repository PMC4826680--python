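import numpy as np
import pytest
from hypothesis import settings

from odlocate import OpticDiscDetector, generate_training_patches
from odlocate.synthetic import PhantomSpec, generate_phantom

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def phantom():
    """Default-spec phantom: vessel-fragmented disc plus two exudates."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def intact_phantom():
    """Phantom whose disc survives thresholding in one piece: few vessels,
    no exudates, so the first detection pass succeeds without dilation."""
    return generate_phantom(PhantomSpec(seed=4, n_vessels=2, n_exudates=0))


@pytest.fixture(scope="session")
def trained_detector():
    """Detector fit on the default synthetic training patches (seed 7)."""
    patches, labels = generate_training_patches(seed=7)
    return OpticDiscDetector(random_state=7).fit(patches, labels)
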