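import numpy as np
import pytest

from fvorient.synthetic import (
    DEFAULT_POSE,
    PoseSpec,
    make_fv,
    make_pmhc,
    make_pose_family,
    scaffold_frame_system,
)


@pytest.fixture(scope="session")
def frame_system():
    """Exact frame system of the noiseless scaffold."""
    return scaffold_frame_system()


@pytest.fixture(scope="session")
def default_fv():
    fv, truth = make_fv(DEFAULT_POSE)
    return fv, truth


@pytest.fixture(scope="session")
def pmhc_complex():
    """Toy class-I complex at a 51.4-degree docking angle, 5 A groove gap."""
    complex_, truth = make_pmhc(51.4, groove_gap=5.0, seed=1)
    return complex_, truth


@pytest.fixture(scope="session")
def pose_families():
    """Two noiseless pose families with HC2 centres 15 degrees apart."""
    fam_a = make_pose_family(PoseSpec(HC2=120.0), spread=2.0, n=20, seed=11)
    fam_b = make_pose_family(PoseSpec(HC2=105.0), spread=2.0, n=20, seed=12)
    return fam_a, fam_b


def rigid_motion(seed: int):
    """A deterministic, non-trivial proper rigid motion for invariance tests."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    from fvorient.geometry import RigidTransform

    return RigidTransform(Q, t)
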