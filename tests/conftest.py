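import numpy as np
import pytest

from agavenet.simulate import StudyDesign, make_study


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated study: 2 x 2 x 2 x 2 = 16 samples, 30 taxa."""
    design = StudyDesign(n_sites=2, n_replicates=2, depth_range=(2000, 4000))
    return make_study(design=design, n_taxa=30, n_genera=20, seed=42)


@pytest.fixture(scope="session")
def default_bundle():
    """The default 48-sample study design."""
    return make_study(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
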