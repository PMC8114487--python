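import numpy as np
import pytest

from matisse.config import SegmentationParams
from matisse.synthetic import Misalignment, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact aligned scene (100x100 um, 40 nuclei) shared across tests."""
    spec = SceneSpec(
        field_size_um=(100.0, 100.0),
        n_nuclei=40,
        min_center_spacing_um=4.0,
        seed=11,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def misaligned_scene():
    """A scene whose IF frame is misaligned by a known similarity."""
    spec = SceneSpec(
        field_size_um=(150.0, 150.0),
        n_nuclei=80,
        min_center_spacing_um=4.0,
        misalignment=Misalignment(scale=1.02, rotation_deg=3.0, translation_um=(8.0, -6.0)),
        seed=5,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def default_seg_params():
    return SegmentationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
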