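import numpy as np
import pytest

from barotraj.model_io import AtomRecord, Structure, Trajectory


def make_atom(serial, name="CA", element="C", residue_name="ALA",
              residue_id=1, chain="A", position=(0.0, 0.0, 0.0)):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_id=residue_id, chain=chain, position=np.asarray(position),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def cloud_structure(rng):
    """50-atom random CA cloud, one residue per atom."""
    coords = rng.normal(0.0, 6.0, size=(50, 3))
    atoms = [
        make_atom(i + 1, residue_id=i + 1, position=coords[i])
        for i in range(50)
    ]
    return Structure(atoms=atoms)


@pytest.fixture
def still_trajectory(cloud_structure):
    """Five identical frames of the random cloud."""
    frames = np.repeat(cloud_structure.coords[None], 5, axis=0)
    return Trajectory(topology=cloud_structure, frames=frames)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2**31)))).as_matrix()
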