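import numpy as np
import pytest
import trimesh

import condylomorph as cm
from condylomorph.block import build_cut_plane, build_frame, cut_block
from condylomorph.geometry import fit_frankfort_plane


@pytest.fixture(scope="session")
def default_condyle() -> cm.GeneratedCondyle:
    """Right-side synthetic condyle at default shape parameters."""
    return cm.generate_condyle(cm.CondyleParams())


@pytest.fixture(scope="session")
def left_condyle() -> cm.GeneratedCondyle:
    return cm.generate_condyle(cm.CondyleParams(side="left"))


def make_frame(landmarks, side):
    fh = fit_frankfort_plane(landmarks["porion_l"], landmarks["porion_r"],
                             landmarks["orbitale"], landmarks["crista_galli"])
    plane_c = build_cut_plane(fh, landmarks[f"s_{side[0]}"],
                              landmarks["crista_galli"])
    frame = build_frame(plane_c, landmarks["porion_l"], landmarks["porion_r"],
                        landmarks["orbitale"], side)
    return fh, plane_c, frame


@pytest.fixture(scope="session")
def default_block(default_condyle) -> cm.CondylarBlock:
    _, plane_c, frame = make_frame(default_condyle.landmarks, "right")
    return cut_block(default_condyle.mesh, plane_c, frame)


@pytest.fixture(scope="session")
def default_measure(default_condyle) -> dict:
    return cm.measure_condyle(default_condyle.mesh, default_condyle.landmarks,
                              "right")


@pytest.fixture(scope="session")
def sphere10() -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
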