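import numpy as np
import pytest

from canopyflux.mesh import MeshResolution, build_canopy_mesh
from canopyflux.scene import BROADLEAF, CONIFER, TreeRecord, scene_from_records
from canopyflux.synth import generate_plot, toy_fixture

STUDY_LATITUDE = 32.076


@pytest.fixture(scope="session")
def single_cone_scene():
    return toy_fixture("single_cone")


@pytest.fixture(scope="session")
def single_ellipsoid_scene():
    return toy_fixture("single_ellipsoid")


@pytest.fixture(scope="session")
def two_tree_scene():
    return toy_fixture("two_tree_shadow")


@pytest.fixture(scope="session")
def conifer_plot():
    return generate_plot("conifer", seed=7)


@pytest.fixture(scope="session")
def conifer_mesh(conifer_plot):
    return build_canopy_mesh(conifer_plot)


def random_small_scene(rng: np.random.Generator, size: float = 20.0):
    """A 2-4 tree mini plot for brute-force-tractable ray tests."""
    n = int(rng.integers(2, 5))
    recs = []
    for i in range(n):
        cls = CONIFER if rng.random() < 0.5 else BROADLEAF
        bole = float(rng.uniform(1.0, 4.0))
        recs.append(TreeRecord(
            tree_id=f"r{i}", species_class=cls,
            center_x=float(rng.uniform(3.0, size - 3.0)),
            center_y=float(rng.uniform(3.0, size - 3.0)),
            clear_bole_height=bole,
            tree_height=bole + float(rng.uniform(3.0, 10.0)),
            half_width_ew=float(rng.uniform(1.5, 4.0)),
            half_width_ns=float(rng.uniform(1.5, 4.0))))
    return scene_from_records(recs, bounds=(0, 0, size, size))


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
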