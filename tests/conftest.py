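import numpy as np
import pytest

from glenax import LandmarkSet, ScapulaMesh, ScapulaParams, generate_scapula


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_mesh() -> ScapulaMesh:
    """Hand-written 8-vertex mesh with every region represented.

    Coordinates are float32-representable so PLY round-trips are exact.
    """
    vertices = np.array(
        [
            [0.0, 0.0, 0.0],  # body
            [1.0, 0.0, 0.0],  # body
            [0.0, 0.0, 1.0],  # spine
            [1.0, 0.0, 1.0],  # spine
            [2.0, 0.5, 0.5],  # glenoid
            [2.0, -0.5, 0.5],  # glenoid
            [1.5, 1.0, 1.5],  # acromion
            [1.75, 1.25, 0.25],  # coracoid
        ]
    )
    faces = np.array(
        [[0, 1, 2], [1, 3, 2], [1, 4, 3], [4, 5, 3], [3, 6, 2], [4, 7, 5]]
    )
    labels = np.array(
        ["body", "body", "spine", "spine", "glenoid", "glenoid", "acromion", "coracoid"]
    )
    return ScapulaMesh(vertices=vertices, faces=faces, labels=labels)


@pytest.fixture
def two_strip_mesh() -> ScapulaMesh:
    """Two 3x2 quad strips (body below, spine above) sharing no vertices.

    The body top row {3, 4, 5} and the spine bottom row {6, 7, 8} are joined
    by faces, so the spine/body boundary is exactly those 6 vertices.  A
    detached glenoid triangle satisfies the mandatory-region invariant.
    """
    xs = [0.0, 1.0, 2.0]
    rows = [-1.0, 0.0, 1.0, 2.0]  # body rows -1, 0; spine rows 1, 2
    vertices = np.array([[x, 0.0, z] for z in rows for x in xs] +
                        [[3.0, 1.0, 0.0], [3.0, -1.0, 0.0], [3.5, 0.0, 1.0]])
    faces = []
    for j in range(3):
        for i in range(2):
            a = 3 * j + i
            faces += [[a, a + 1, a + 3], [a + 1, a + 4, a + 3]]
    faces.append([12, 13, 14])
    labels = np.array(["body"] * 6 + ["spine"] * 6 + ["glenoid"] * 3)
    return ScapulaMesh(vertices=vertices, faces=np.array(faces), labels=labels)


@pytest.fixture
def landmarks() -> LandmarkSet:
    return LandmarkSet(
        trigonum=[-100.0, 0.0, 0.0],
        glenoid_upper_apex=[0.0, 0.0, 12.0],
        glenoid_lower_apex=[0.0, 0.0, -12.0],
        fossa_points=[[-80, 0, 0], [-65, 0, 0], [-50, 0, 0], [-35, 0, 0], [-20, 0, 0]],
        inferior_angle=[-90.0, 0.0, -95.0],
        rater_id="r1",
    )


@pytest.fixture
def canonical_case():
    """Default synthetic scapula at +10 deg true inclination."""
    return generate_scapula(ScapulaParams(true_inclination_deg=10.0))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
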