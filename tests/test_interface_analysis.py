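import dataclasses
import math

import numpy as np
import pytest

from ubiqpair import interface_analysis as ia
from ubiqpair.conformation_analysis import CrossoverHelix, secondary_structure
from ubiqpair.interface_analysis import (
    InterfaceError,
    detect_hbonds,
    detect_linchpin,
    e3_engagement,
    find_e2_binding_loop,
    interface_residues,
    interface_rmsd,
)
from ubiqpair.structure_model import Copy, TernaryComplex
from ubiqpair.synthetic_fixtures import ComplexSpec, make_complex

from conftest import chain_from_ca, ideal_helix_ca, random_rotation


def _polar(r, theta):
    return [r * math.cos(theta), r * math.sin(theta), 0.0]


# ---------------------------------------------------------------------------
# Interface residues
# ---------------------------------------------------------------------------

class TestInterfaceResidues:
    def test_distant_chains_empty(self):
        a = chain_from_ca("A", [[0, 0, 0], [3, 0, 0]])
        b = chain_from_ca("B", [[50, 0, 0], [53, 0, 0]])
        assert interface_residues(a, b).residues == frozenset()

    def test_single_pair_at_7_9(self):
        a = chain_from_ca("A", [[0, 0, 0], [0, 30, 0], [0, 60, 0]])
        b = chain_from_ca("B", [[7.9, 0, 0], [7.9, 30, 100], [7.9, 60, 100]])
        iface = interface_residues(a, b)
        assert iface.residues == frozenset({("A", 1), ("B", 1)})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = chain_from_ca("A", rng.uniform(0, 25, size=(40, 3)))
        b = chain_from_ca("B", rng.uniform(5, 30, size=(35, 3)))
        iface = interface_residues(a, b)
        expected = set()
        for ra in a.residues:
            for rb in b.residues:
                if np.linalg.norm(ra.ca - rb.ca) <= 8.0:
                    expected.add(("A", ra.number))
                    expected.add(("B", rb.number))
        assert set(iface.residues) == expected


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

class TestHbonds:
    def test_pair_at_3_4_detected(self):
        a = chain_from_ca("A", [[0, 0, 0]], with_backbone=False)
        b = chain_from_ca("B", [[30, 0, 0]], with_backbone=False)
        a.residues[0].atoms["N"] = dataclasses.replace(
            a.residues[0].atoms["CA"], atom_name="N", element="N")
        b.residues[0].atoms["O"] = dataclasses.replace(
            b.residues[0].atoms["CA"], atom_name="O", element="O",
            coords=np.array([3.4, 0.0, 0.0]), chain_id="B")
        bonds = detect_hbonds(a, b)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.4)
        assert bonds[0].donor[2] == "N"

    def test_pair_at_3_6_rejected(self):
        a = chain_from_ca("A", [[0, 0, 0]], with_backbone=False)
        b = chain_from_ca("B", [[30, 0, 0]], with_backbone=False)
        a.residues[0].atoms["N"] = dataclasses.replace(
            a.residues[0].atoms["CA"], atom_name="N", element="N")
        b.residues[0].atoms["O"] = dataclasses.replace(
            b.residues[0].atoms["CA"], atom_name="O", element="O",
            coords=np.array([3.6, 0.0, 0.0]))
        assert detect_hbonds(a, b) == []

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = chain_from_ca("A", rng.uniform(0, 15, size=(12, 3)))
        b = chain_from_ca("B", rng.uniform(2, 17, size=(12, 3)))
        bonds = detect_hbonds(a, b)
        expected = 0
        for ra in a.residues:
            for rb in b.residues:
                for atom_a in ra.polar_atoms():
                    for atom_b in rb.polar_atoms():
                        if np.linalg.norm(atom_a.coords - atom_b.coords) <= 3.5:
                            expected += 1
        assert len(bonds) == expected

    def test_chain_swap_invariance(self):
        rng = np.random.default_rng(9)
        a = chain_from_ca("A", rng.uniform(0, 15, size=(10, 3)))
        b = chain_from_ca("B", rng.uniform(2, 17, size=(10, 3)))
        assert len(detect_hbonds(a, b)) == len(detect_hbonds(b, a))


# ---------------------------------------------------------------------------
# E2 binding loop
# ---------------------------------------------------------------------------

class TestE2BindingLoop:
    def _chain_with_coil(self, n_coil):
        """Coil of n_coil residues ending right before a helix at 98."""
        coil = [[-2.5 * (98 - i), 4.0 + 1.2 * ((-1) ** i), 0.0]
                for i in range(98 - n_coil, 98)]
        helix = ideal_helix_ca(16)
        return chain_from_ca("B", np.vstack([coil, helix]), start=98 - n_coil)

    def test_coil_of_8_returned(self):
        chain = self._chain_with_coil(8)
        helix = CrossoverHelix("B", 98, 113, "curated")
        # first coil residue lacks an upstream neighbour and stays coil
        assert find_e2_binding_loop(chain, helix) == (90, 97)

    def test_long_coil_capped_at_12(self):
        chain = self._chain_with_coil(20)
        helix = CrossoverHelix("B", 98, 113, "curated")
        assert find_e2_binding_loop(chain, helix) == (86, 97)

    def test_override_returned(self):
        chain = self._chain_with_coil(8)
        helix = CrossoverHelix("B", 98, 113, "curated")
        assert find_e2_binding_loop(chain, helix, override=(91, 96)) == (91, 96)

    def test_helix_at_chain_start(self):
        chain = chain_from_ca("B", ideal_helix_ca(16), start=98)
        helix = CrossoverHelix("B", 98, 113, "curated")
        assert find_e2_binding_loop(chain, helix) is None

    def test_upstream_strand_bounds_loop(self, refs, closed_complex):
        complex, _ = closed_complex
        e2 = complex.chain("B")
        helix = CrossoverHelix("B", 23, 38, "curated")
        loop = find_e2_binding_loop(e2, helix)
        assert loop == (13, 22)


# ---------------------------------------------------------------------------
# E3 loop engagement
# ---------------------------------------------------------------------------

def _engagement_fixture(arc1, arc2=None):
    """E2 'loop' = one residue at the origin; E3 = coil arcs at radius 6 with
    strand excursions to radius 20 between them."""
    coords = [_polar(6.0, k * 0.5) for k in range(arc1)]
    theta = (arc1 - 1) * 0.5
    for k in range(1, 5):
        coords.append(_polar(6.0 + 3.5 * k, theta))
    if arc2 is not None:
        r_far = 6.0 + 3.5 * 4
        for k in range(1, 4):
            coords.append(_polar(r_far, theta + k * (3.0 / r_far)))
        theta_in = theta + 3 * (3.0 / r_far) + 1.2
        for k in range(1, 4):
            coords.append(_polar(r_far - 3.5 * k, theta_in))
        for k in range(arc2):
            coords.append(_polar(6.0, theta_in + (k + 1) * 0.5))
    else:
        for k in range(1, 3):
            coords.append(_polar(6.0 + 3.5 * 4 + 3.7 * k, theta))
    e2 = chain_from_ca("B", [[0.0, 0.0, 0.0]])
    e3 = chain_from_ca("C", coords)
    complex = TernaryComplex("t", {"B": e2, "C": e3})
    complex.copies = [Copy("B", "B", "C")]
    return complex


def _engagement_oracle(complex, e2_loop):
    """Independent region scan + coil-segment count."""
    e2 = complex.chain("B")
    e3 = complex.chain("C")
    loop_atoms = [a.coords for res in e2.residues
                  if e2_loop[0] <= res.number <= e2_loop[1]
                  for a in res.atoms.values()]
    region = set()
    for res in e3.residues:
        for atom in res.atoms.values():
            if any(np.linalg.norm(atom.coords - c) <= 8.0 for c in loop_atoms):
                region.add(res.number)
                break
    labels = secondary_structure(e3)
    n_res = sum(1 for res in e3.residues
                if res.number in region and labels[res.key] == "C")
    segments = 0
    current = set()
    for res in e3.residues:
        if labels[res.key] == "C":
            current.add(res.number)
        else:
            if current & region:
                segments += 1
            current = set()
    if current & region:
        segments += 1
    return segments, n_res


class TestE3Engagement:
    def test_distant_e3_is_zero(self, refs, closed_complex):
        complex, _ = closed_complex
        e3 = complex.chain("C")
        for res in e3.residues:
            for name, atom in list(res.atoms.items()):
                res.atoms[name] = dataclasses.replace(
                    atom, coords=atom.coords + np.array([0.0, 0.0, 100.0]))
        engagement = e3_engagement(complex, complex.copies[0], (13, 22))
        assert (engagement.n_e3_loops, engagement.n_e3_loop_residues) == (0, 0)

    def test_single_5_residue_loop(self):
        complex = _engagement_fixture(arc1=5)
        engagement = e3_engagement(complex, complex.copies[0], (1, 1))
        assert (engagement.n_e3_loops, engagement.n_e3_loop_residues) == (1, 5)

    def test_two_disjoint_loops_3_and_4(self):
        # arc2's first residue sits next to the returning strand and is labeled
        # E, so 5 placed residues give 4 engaged coil residues
        complex = _engagement_fixture(arc1=3, arc2=5)
        engagement = e3_engagement(complex, complex.copies[0], (1, 1))
        oracle = _engagement_oracle(complex, (1, 1))
        assert (engagement.n_e3_loops, engagement.n_e3_loop_residues) == oracle
        assert oracle == (2, 7)

    def test_monotone_under_translation(self):
        complex = _engagement_fixture(arc1=5)
        e3 = complex.chain("C")
        last = e3_engagement(complex, complex.copies[0], (1, 1))
        for _ in range(6):
            for res in e3.residues:
                for name, atom in list(res.atoms.items()):
                    res.atoms[name] = dataclasses.replace(
                        atom, coords=atom.coords + np.array([0.0, 0.0, 1.5]))
            engagement = e3_engagement(complex, complex.copies[0], (1, 1))
            assert engagement.n_e3_loop_residues <= last.n_e3_loop_residues
            assert engagement.n_e3_loops <= last.n_e3_loops or \
                engagement.n_e3_loop_residues < last.n_e3_loop_residues
            last = engagement

    def test_counts_invariant(self):
        complex = _engagement_fixture(arc1=5)
        engagement = e3_engagement(complex, complex.copies[0], (1, 1))
        assert engagement.n_e3_loop_residues >= engagement.n_e3_loops


# ---------------------------------------------------------------------------
# Linchpin detection
# ---------------------------------------------------------------------------

class TestLinchpin:
    def test_planted_bridge_detected(self, refs, closed_complex):
        complex, _ = closed_complex
        call = detect_linchpin(complex, refs)
        assert call.present
        assert call.residue == ("C", 12, "ARG")
        assert call.fraction_of_copies == 1.0

    def test_rotated_side_chain_absent(self, refs):
        complex, _ = make_complex(ComplexSpec("closed", 7.0, 4.0, with_linchpin=False))
        call = detect_linchpin(complex, refs)
        assert not call.present
        assert call.residue is None

    def test_binary_complex_undefined(self, refs):
        complex, _ = make_complex(ComplexSpec("closed", 7.0, 4.0), include_e3=False)
        assert detect_linchpin(complex, refs) is None

    def test_deterministic(self, refs, closed_complex):
        complex, _ = closed_complex
        first = detect_linchpin(complex, refs)
        second = detect_linchpin(complex, refs)
        assert first == second

    def test_half_of_copies_rule(self, refs):
        complex, _ = make_complex(ComplexSpec("closed", 7.0, 4.0, n_copies=2))
        # break the bridge in the second copy only -> fraction 0.5, still present
        e3 = complex.chain("F")
        arg = e3.residue_by_number(12)
        for name in ("NH1", "NH2"):
            arg.atoms[name] = dataclasses.replace(
                arg.atoms[name], coords=arg.atoms[name].coords + np.array([0, 0, 50.0]))
        call = detect_linchpin(complex, refs)
        assert call.fraction_of_copies == 0.5
        assert call.present


# ---------------------------------------------------------------------------
# Interface RMSD
# ---------------------------------------------------------------------------

class TestInterfaceRMSD:
    def test_identity_is_zero(self, refs):
        a, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        b, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        result = interface_rmsd(a, b, refs)
        assert result.overall == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in result.per_interface.values())

    def test_rigid_transform_is_zero(self, refs):
        a, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        rng = np.random.default_rng(11)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-30, 30, size=3)
            result = interface_rmsd(a, a.transformed(R, t), refs)
            assert result.overall == pytest.approx(0.0, abs=1e-6)

    def test_known_displacement(self, refs):
        """Displacing only the ubiquitin chain by v yields RMSD values that
        follow in closed form from interface membership."""
        a, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        b, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        v = np.array([0.3, -0.2, 0.1])
        ub = b.chain("A")
        for res in ub.residues:
            for name, atom in list(res.atoms.items()):
                res.atoms[name] = dataclasses.replace(atom, coords=atom.coords + v)
        result = interface_rmsd(a, b, refs)
        v_norm = float(np.linalg.norm(v))
        for pair, roles in (("UB-E2", ("A", "B")), ("UB-E3", ("A", "C"))):
            if pair not in result.per_interface:
                continue
            iface_a = interface_residues(a.chain(roles[0]), a.chain(roles[1]))
            iface_b = interface_residues(b.chain(roles[0]), b.chain(roles[1]))
            keys = set(iface_a.residues) | set(iface_b.residues)
            n_ub = sum(1 for cid, _ in keys if cid == "A")
            n_total = len(keys)
            expected = v_norm * math.sqrt(n_ub / n_total)
            assert result.per_interface[pair] == pytest.approx(expected, abs=1e-6)
        # E2-E3 interface is untouched
        assert result.per_interface["E2-E3"] == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_anchor_raises(self, refs):
        a, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        b, _ = make_complex(ComplexSpec("closed", 7.0, 4.0))
        e2 = b.chain("B")
        for number in range(23, 37):
            del e2.residue_by_number(number).atoms["CA"]
        with pytest.raises(InterfaceError):
            interface_rmsd(a, b, refs)

    def test_unknown_interface_name(self, closed_complex):
        complex, _ = closed_complex
        with pytest.raises(InterfaceError):
            ia._copy_chain_pair(complex, complex.copies[0], "E1-E2")
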