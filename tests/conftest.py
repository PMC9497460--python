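import numpy as np
import pytest

import psmaseg as ps


@pytest.fixture(scope="session")
def tiny_spec() -> ps.PhantomSpec:
    """Small phantom: one lesion per class plus one benign bone focus."""
    return ps.PhantomSpec(
        grid_shape=(32, 32, 32),
        lesions_per_class=(1, 1, 1),
        n_unspecific_bone_foci=1,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_spec) -> ps.PetCtStudy:
    return ps.generate_study(tiny_spec)


@pytest.fixture(scope="session")
def prep_study(tiny_study) -> ps.PetCtStudy:
    return ps.preprocess_study(tiny_study)


@pytest.fixture(scope="session")
def small_model() -> ps.VoxelClassifier:
    cfg = ps.ModelConfig(n_input_channels=6, encoder_depth=2, base_filters=4)
    return ps.build_model(cfg, seed=0)


def make_labelmap(data, spacing=(1.0, 1.0, 1.0)) -> ps.LabelMap:
    return ps.LabelMap(np.asarray(data, dtype=np.int16), spacing)


@pytest.fixture
def sphere_labelmap() -> ps.LabelMap:
    """One spherical prostate lesion on a 16^3 grid."""
    shape = (16, 16, 16)
    g = np.ogrid[:16, :16, :16]
    sphere = sum((a - 8) ** 2 for a in g) <= 9
    data = np.where(sphere, 1, 0).astype(np.int16)
    return ps.LabelMap(data, (1.0, 1.0, 1.0))
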