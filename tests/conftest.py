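import numpy as np
import pytest

from casite.structure_io import DEFAULT_TABLE, assemble_structure
from casite.synthetic import (
    build_residue,
    canonical_triad_geometry,
    move_residue,
)
from casite.template_model import DEFAULT_FUZZ, build_template


@pytest.fixture(scope="session")
def table():
    return DEFAULT_TABLE


@pytest.fixture(scope="session")
def fuzz():
    return DEFAULT_FUZZ


@pytest.fixture()
def triad_residues():
    """Idealized Ser-His-Asp site, fresh copies per test."""
    return canonical_triad_geometry()


@pytest.fixture()
def triad_structure(triad_residues):
    return assemble_structure("triad", {"A": triad_residues})


@pytest.fixture()
def triad_functional(triad_residues):
    return build_template(triad_residues, "functional", template_id="triad_f")


@pytest.fixture()
def triad_backbone(triad_residues):
    return build_template(triad_residues, "backbone", template_id="triad_b")


def random_coords(rng: np.random.Generator, n: int, spread: float = 5.0) -> np.ndarray:
    return rng.uniform(-spread, spread, size=(n, 3))


def random_rigid(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-10, 10, size=3)
    return R, t


def place_residues(residues, spacing=8.0):
    """Spread local-frame residues along x so they never overlap."""
    return [
        move_residue(r, np.eye(3), np.array([i * spacing, 0.0, 0.0]))
        for i, r in enumerate(residues)
    ]
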