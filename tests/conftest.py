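"""Shared fixtures: tiny structures and trajectories built in memory."""

import numpy as np
import pytest

from allodyn._elements import ELEMENT_MASS, ELEMENT_VDW
from allodyn.trajio import Atom, Structure, Trajectory

TOY_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  GLY B   1      10.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   ALA B   2      13.800   0.000   0.000  1.00  0.00           N
END
"""


def make_atom(i, name="CA", element="C", residue_index=None, chain="A",
              charge=0.0, radius=None, epsilon=0.0, mass=None):
    residue_index = i if residue_index is None else residue_index
    return Atom(
        serial=i + 1,
        name=name,
        element=element,
        residue_index=residue_index,
        residue_name="GLY",
        residue_seq=residue_index + 1,
        chain_id=chain,
        mass=ELEMENT_MASS[element] if mass is None else mass,
        charge=charge,
        vdw_radius=ELEMENT_VDW[element] if radius is None else radius,
        lj_epsilon=epsilon,
    )


def make_structure(coords, chains=None, **atom_kwargs):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    chains = chains or ["A"] * n
    atoms = []
    res_in_chain: dict = {}
    for i in range(n):
        res_in_chain.setdefault(chains[i], 0)
        atoms.append(
            make_atom(i, residue_index=i, chain=chains[i], **atom_kwargs)
        )
    return Structure(atoms=atoms, coordinates=coords)


def make_trajectory(frames, chains=None, **atom_kwargs):
    frames = np.asarray(frames, dtype=float)
    structure = make_structure(frames[0], chains=chains, **atom_kwargs)
    return Trajectory(structure=structure, frames=frames)


@pytest.fixture
def toy_pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def two_chain_pdb_path(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform-ish random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
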