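import numpy as np
import pytest

import eggshade as eg


@pytest.fixture(scope="session")
def small_bank():
    """Geometrically similar bank at sigma = {2, 4} px for fast unit tests."""
    return eg.build_filter_bank(scales=(16.0, 32.0), scale_factor=0.125)


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default nest scene (3 eggs, 512 px, px_per_cm 10)."""
    return eg.render_scene(eg.SceneParams(rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
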