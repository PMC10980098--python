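import numpy as np
import pytest

from pepforge import ComplexStructure, ResidueRecord, Atom3D
from pepforge.fixtures import ToySpec, make_toy_complex, make_recovery_landscape


@pytest.fixture(scope="session")
def docked_toy():
    return make_toy_complex(ToySpec(rng_seed=1))


@pytest.fixture(scope="session")
def separated_toy():
    return make_toy_complex(ToySpec(decoy_mode="separated", rng_seed=1))


@pytest.fixture(scope="session")
def clashing_toy():
    return make_toy_complex(ToySpec(decoy_mode="clashing", rng_seed=1))


@pytest.fixture(scope="session")
def landscape():
    return make_recovery_landscape("LKWFAN", rng_seed=3)


def single_atom_residue(chain_id, seq_index, position, radius=1.7, name="CA"):
    return ResidueRecord(
        chain_id=chain_id,
        seq_index=seq_index,
        res_name="ALA",
        atoms=(Atom3D(name=name, element="C", position=np.asarray(position, float),
                      vdw_radius=radius),),
    )


def two_atom_complex(d, radius=1.7):
    """One protein atom at the origin, one peptide atom at distance d on x."""
    return ComplexStructure(
        protein=(single_atom_residue("A", 1, [0, 0, 0], radius),),
        peptide=(single_atom_residue("B", 1, [d, 0, 0], radius),),
    )


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
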