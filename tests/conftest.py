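import numpy as np
import pytest

from episeg import synthetic


@pytest.fixture(scope="session")
def small_scene_config():
    """256 px scene with several glands of each morphology."""
    return synthetic.SceneConfig(
        canvas=256, n_benign=3, n_small_malignant=5, n_single_cell=6,
        benign_radius=(20.0, 30.0), malignant_radius=(7.0, 12.0),
    )


@pytest.fixture(scope="session")
def scene(small_scene_config):
    return synthetic.generate_scene(small_scene_config, seed=11)


@pytest.fixture(scope="session")
def ihc_rendering(scene):
    return synthetic.render(scene, "IHC")


@pytest.fixture(scope="session")
def he_rendering(scene):
    return synthetic.render(scene, "HE")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
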