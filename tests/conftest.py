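import numpy as np
import pytest

from kneemap import SyntheticBoneSpec, make_bone_mesh


@pytest.fixture(scope="session")
def femur():
    mesh, anchors = make_bone_mesh(SyntheticBoneSpec(bone="femur"))
    return mesh, anchors


@pytest.fixture(scope="session")
def tibia():
    mesh, anchors = make_bone_mesh(SyntheticBoneSpec(bone="tibia"))
    return mesh, anchors


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
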