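import math

import numpy as np
import pytest

from ubiqpair.structure_model import AtomRecord, Chain, Residue, TernaryComplex
from ubiqpair.synthetic_fixtures import ComplexSpec, make_complex, toy_registry


def chain_from_ca(chain_id, ca_coords, start=1, res_names=None, with_backbone=True):
    """Build a chain from CA coordinates; optional N/C/O atoms at small fixed
    offsets (kept within 0.85 A of the CA)."""
    n_off = np.array([0.5, 0.5, 0.3])
    c_off = np.array([-0.5, -0.5, 0.3])
    o_off = np.array([-0.5, 0.5, -0.3])
    residues = []
    for i, ca in enumerate(ca_coords):
        number = start + i
        name = (res_names[i] if res_names else "ALA")
        atoms = {}

        def add(atom_name, element, coords):
            atoms[atom_name] = AtomRecord(chain_id, number, "", name, atom_name,
                                          element, np.asarray(coords, float))

        add("CA", "C", ca)
        if with_backbone:
            add("N", "N", np.asarray(ca) + n_off)
            add("C", "C", np.asarray(ca) + c_off)
            add("O", "O", np.asarray(ca) + o_off)
        residues.append(Residue(number, "", name, atoms))
    return Chain(chain_id, residues)


def ideal_helix_ca(n, rise=1.5, turn_deg=100.0, radius=2.3, x0=0.0):
    """Analytic alpha-helix CA trace along +x."""
    coords = []
    for k in range(n):
        theta = math.radians(turn_deg * k)
        coords.append([x0 + rise * k, radius * math.cos(theta), radius * math.sin(theta)])
    return np.asarray(coords)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture(scope="session")
def refs():
    return toy_registry()


@pytest.fixture(scope="session")
def refs_with_cysless():
    return toy_registry(include_cysless_e2=True)


@pytest.fixture()
def closed_complex():
    complex, manifest = make_complex(ComplexSpec("closed", 7.0, 4.0, with_linchpin=True))
    return complex, manifest


@pytest.fixture()
def open_complex():
    complex, manifest = make_complex(ComplexSpec("open", 15.0, 20.0, with_linchpin=False))
    return complex, manifest
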