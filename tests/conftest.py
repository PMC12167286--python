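import numpy as np
import pytest

from hsisynth.hsi_io import HsiCube, LabelLegend, SemanticMask
from hsisynth.phantom import PhantomConfig, make_dataset, make_spectral_library


@pytest.fixture(scope="session")
def small_library():
    return make_spectral_library(n_classes=5, n_bands=25, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(n_subjects=3, images_per_subject=2, H=32, W=32, C=25,
                         n_organ_classes=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_library):
    return make_dataset(small_config, small_library)


@pytest.fixture
def tiny_cube():
    rng = np.random.default_rng(0)
    return HsiCube(
        data=rng.uniform(0.1, 0.9, (4, 4, 3)).astype(np.float32),
        wavelengths=[500.0, 505.0, 510.0],
        subject_id="pig_01",
        camera_id="cam_a",
    )


@pytest.fixture
def tiny_mask():
    legend = LabelLegend(entries={0: "blue cloth", 1: "liver"}, background_id=0)
    return SemanticMask(labels=np.array([[0, 1], [1, 0]]), legend=legend)
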