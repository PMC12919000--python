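"""Interface residues, hydrogen bonds, linchpin calls, E3 loop engagement and
interface RMSD.

Hydrogen-bond detection is deliberately distance-only: any inter-chain pair of
nitrogen/oxygen heavy atoms within 3.5 A counts as one bond (no hydrogen
placement, no angular term, sulfur excluded).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .conformation_analysis import (
    UB_CTERM,
    UB_TAIL_START,
    CrossoverHelix,
    find_crossover_helix,
    secondary_structure,
)
from .structure_model import Chain, Copy, ReferenceSequences, Role, TernaryComplex

__all__ = [
    "INTERFACE_CUTOFF",
    "HBOND_CUTOFF",
    "INTERFACE_NAMES",
    "InterfaceResidueSet",
    "HydrogenBond",
    "LinchpinCall",
    "LoopEngagement",
    "InterfaceRMSDResult",
    "InterfaceError",
    "interface_residues",
    "detect_hbonds",
    "find_e2_binding_loop",
    "e3_engagement",
    "detect_linchpin",
    "interface_rmsd",
]

INTERFACE_CUTOFF = 8.0
HBOND_CUTOFF = 3.5
E2_LOOP_MAX_LEN = 12
INTERFACE_NAMES = ("UB-E2", "UB-E3", "E2-E3")


class InterfaceError(ValueError):
    pass


@dataclass(frozen=True)
class InterfaceResidueSet:
    interface: str
    residues: frozenset  # of (chain_id, residue_number)
    cutoff: float = INTERFACE_CUTOFF

    def for_chain(self, chain_id: str) -> set[int]:
        return {num for cid, num in self.residues if cid == chain_id}


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[str, int, str]     # (chain, residue number, atom name)
    acceptor: tuple[str, int, str]
    distance: float


@dataclass(frozen=True)
class LinchpinCall:
    present: bool
    residue: Optional[tuple[str, int, str]]  # (chain, residue number, residue name)
    fraction_of_copies: float


@dataclass(frozen=True)
class LoopEngagement:
    n_e3_loops: int
    n_e3_loop_residues: int
    e2_binding_loop: Optional[tuple[int, int]]


@dataclass(frozen=True)
class InterfaceRMSDResult:
    per_interface: dict
    overall: float
    n_common_residues: int


def _copy_chain_pair(complex: TernaryComplex, copy: Copy, pair: str) -> tuple[Chain, Chain]:
    lookup = {
        "UB-E2": (copy.ub_chain, copy.e2_chain),
        "UB-E3": (copy.ub_chain, copy.e3_chain),
        "E2-E3": (copy.e2_chain, copy.e3_chain),
    }
    if pair not in lookup:
        raise InterfaceError(f"unknown interface {pair!r}; expected one of {INTERFACE_NAMES}")
    a, b = lookup[pair]
    if a is None or b is None:
        raise InterfaceError(f"interface {pair} undefined: missing chain in copy {copy}")
    return complex.chain(a), complex.chain(b)


def interface_residues(chain_a: Chain, chain_b: Chain, interface: str = "",
                       cutoff: float = INTERFACE_CUTOFF) -> InterfaceResidueSet:
    """Residues of both chains whose Calpha lies within ``cutoff`` of a
    Calpha in the partner chain. Symmetric; the empty set is valid."""
    res_a, ca_a = chain_a.ca_array()
    res_b, ca_b = chain_b.ca_array()
    members: set[tuple[str, int]] = set()
    if len(ca_a) and len(ca_b):
        dists = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
        ai, bi = np.where(dists <= cutoff)
        for i in ai:
            members.add((chain_a.chain_id, res_a[i].number))
        for j in bi:
            members.add((chain_b.chain_id, res_b[j].number))
    return InterfaceResidueSet(interface or f"{chain_a.chain_id}-{chain_b.chain_id}",
                               frozenset(members), cutoff)


def _polar_atoms(chain: Chain) -> list:
    atoms = []
    for res in chain.residues:
        atoms.extend(res.polar_atoms())
    return atoms


def detect_hbonds(chain_a: Chain, chain_b: Chain,
                  cutoff: float = HBOND_CUTOFF) -> list[HydrogenBond]:
    """All inter-chain N/O heavy-atom pairs within ``cutoff``, one bond per
    atom pair. By convention the nitrogen (or the chain_a atom for O-O pairs)
    is reported as the donor."""
    atoms_a = _polar_atoms(chain_a)
    atoms_b = _polar_atoms(chain_b)
    bonds: list[HydrogenBond] = []
    if not atoms_a or not atoms_b:
        return bonds
    coords_a = np.asarray([a.coords for a in atoms_a])
    coords_b = np.asarray([a.coords for a in atoms_b])
    dists = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    for i, j in zip(*np.where(dists <= cutoff)):
        a, b = atoms_a[i], atoms_b[j]
        donor, acceptor = (a, b) if (a.element == "N" or b.element != "N") else (b, a)
        bonds.append(HydrogenBond(
            donor=(donor.chain_id, donor.residue_number, donor.atom_name),
            acceptor=(acceptor.chain_id, acceptor.residue_number, acceptor.atom_name),
            distance=float(dists[i, j]),
        ))
    bonds.sort(key=lambda hb: (hb.donor, hb.acceptor))
    return bonds


def find_e2_binding_loop(e2_chain: Chain, helix: CrossoverHelix,
                         override: Optional[tuple[int, int]] = None,
                         max_len: int = E2_LOOP_MAX_LEN) -> Optional[tuple[int, int]]:
    """The coil region immediately N-terminal of the crossover helix.

    Walks upstream from helix.start - 1 through coil residues, stopping at the
    first helix/strand residue or after ``max_len`` residues. Returns None
    (with nothing to walk) when the helix starts at the chain start.
    """
    if override is not None:
        return override
    labels = secondary_structure(e2_chain)
    by_number = {res.number: res for res in e2_chain.residues}
    end = helix.start - 1
    if end not in by_number:
        return None
    span: list[int] = []
    num = end
    while num in by_number and len(span) < max_len:
        if labels.get(by_number[num].key, "C") != "C":
            break
        span.append(num)
        num -= 1
    if not span:
        return None
    return (span[-1], span[0])


def _heavy_coords(chain: Chain, numbers: Optional[set[int]] = None) -> np.ndarray:
    coords = []
    for res in chain.residues:
        if numbers is None or res.number in numbers:
            hc = res.heavy_coords()
            if len(hc):
                coords.append(hc)
    return np.concatenate(coords) if coords else np.empty((0, 3))


def e3_interaction_region(e3_chain: Chain, e2_chain: Chain,
                          e2_loop: tuple[int, int],
                          cutoff: float = INTERFACE_CUTOFF) -> set[int]:
    """E3 residues with any heavy atom within ``cutoff`` of any heavy atom of
    the E2 binding loop."""
    loop_numbers = set(range(e2_loop[0], e2_loop[1] + 1))
    loop_coords = _heavy_coords(e2_chain, loop_numbers)
    region: set[int] = set()
    if not len(loop_coords):
        return region
    for res in e3_chain.residues:
        hc = res.heavy_coords()
        if len(hc) and np.min(
                np.linalg.norm(hc[:, None, :] - loop_coords[None, :, :], axis=2)) <= cutoff:
            region.add(res.number)
    return region


def e3_engagement(complex: TernaryComplex, copy: Copy,
                  e2_loop: tuple[int, int],
                  cutoff: float = INTERFACE_CUTOFF) -> LoopEngagement:
    """Count E3 loop (coil) residues and distinct loop segments engaging the
    E2 binding loop."""
    if copy.e3_chain is None:
        return LoopEngagement(0, 0, e2_loop)
    e3 = complex.chain(copy.e3_chain)
    e2 = complex.chain(copy.e2_chain)
    region = e3_interaction_region(e3, e2, e2_loop, cutoff)
    if not region:
        return LoopEngagement(0, 0, e2_loop)
    labels = secondary_structure(e3)
    # maximal coil runs along the chain
    n_loops = 0
    n_loop_residues = 0
    in_engaged_run = False
    prev_coil = False
    for res in e3.residues:
        coil = labels.get(res.key, "C") == "C"
        if coil and not prev_coil:
            in_engaged_run = False
        if coil and res.number in region:
            n_loop_residues += 1
            if not in_engaged_run:
                n_loops += 1
                in_engaged_run = True
        if not coil:
            in_engaged_run = False
        prev_coil = coil
    return LoopEngagement(n_loops, n_loop_residues, e2_loop)


def _ub_tail_numbers(ub_chain: Chain) -> set[int]:
    numbers = set()
    for pos in range(UB_TAIL_START, UB_CTERM + 1):
        res = ub_chain.ub_residue(pos)
        if res is not None:
            numbers.add(res.number)
    return numbers


def _copy_linchpin(complex: TernaryComplex, copy: Copy,
                   refs: Optional[ReferenceSequences]) -> Optional[tuple[str, int, str]]:
    ub = complex.chain(copy.ub_chain)
    e2 = complex.chain(copy.e2_chain)
    e3 = complex.chain(copy.e3_chain)
    entry = None
    if refs is not None and e2.role is not None and e2.role.gene:
        entry = refs.e2_registry.get(e2.role.gene)
    helix = find_crossover_helix(e2, registry_entry=entry)
    loop = find_e2_binding_loop(e2, helix)
    if loop is None:
        return None
    region = e3_interaction_region(e3, e2, loop)
    if not region:
        return None
    tail_numbers = _ub_tail_numbers(ub)
    e3_to_ub = detect_hbonds(e3, ub)
    e3_to_e2 = detect_hbonds(e3, e2)

    def e3_residues(bonds, partner_filter=None):
        out = set()
        for hb in bonds:
            for endpoint, other in ((hb.donor, hb.acceptor), (hb.acceptor, hb.donor)):
                if endpoint[0] == e3.chain_id and (
                        partner_filter is None or other[1] in partner_filter):
                    out.add(endpoint[1])
        return out

    tail_bonded = e3_residues(e3_to_ub, tail_numbers)
    e2_bonded = e3_residues(e3_to_e2)
    bridging = sorted(region & tail_bonded & e2_bonded)
    if not bridging:
        return None
    number = bridging[0]
    res = e3.residue_by_number(number)
    return (e3.chain_id, number, res.name if res else "UNK")


def detect_linchpin(complex: TernaryComplex,
                    refs: Optional[ReferenceSequences] = None) -> Optional[LinchpinCall]:
    """Structure-level linchpin call.

    A copy has a linchpin when at least one E3 residue inside the
    E2-interaction region hydrogen-bonds both the ubiquitin tail (canonical
    residues 71-76) and the E2. The structure is linchpin-positive when at
    least half of its ternary copies have one. Returns None for binary
    complexes with no E3 copy.
    """
    ternary = [c for c in complex.copies if c.e3_chain is not None]
    if not ternary:
        return None
    hits = [_copy_linchpin(complex, copy, refs) for copy in ternary]
    found = [h for h in hits if h is not None]
    fraction = len(found) / len(ternary)
    present = fraction >= 0.5
    residue = None
    if present and found:
        counts = Counter(found)
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0][1]))
        residue = best[0]
    return LinchpinCall(present=present, residue=residue, fraction_of_copies=fraction)


# ---------------------------------------------------------------------------
# Interface RMSD
# ---------------------------------------------------------------------------

def _role_chain(complex: TernaryComplex, copy: Copy, role: Role) -> Optional[Chain]:
    cid = {Role.UBIQUITIN: copy.ub_chain, Role.E2: copy.e2_chain, Role.E3: copy.e3_chain}[role]
    return None if cid is None else complex.chain(cid)


def _role_residue_key(chain: Chain, number: int, role: Role) -> tuple:
    """Normalize to canonical numbering for ubiquitin chains."""
    if role == Role.UBIQUITIN and chain.ub_map is not None:
        for canonical, res in chain.ub_map.items():
            if res.number == number:
                return (role.value, canonical)
    return (role.value, number)


def interface_rmsd(reference: TernaryComplex, model: TernaryComplex,
                   refs: Optional[ReferenceSequences] = None,
                   cutoff: float = INTERFACE_CUTOFF) -> InterfaceRMSDResult:
    """Interface RMSD between a reference and a model complex.

    The rigid fit uses only paired crossover-helix Calpha atoms (matched by
    author residue number); RMSDs are then computed over Calpha atoms of
    interface residues (8 A rule, union of the two structures' interface
    sets) resolved in both structures, per interface and overall.
    """
    if not reference.copies or not model.copies:
        raise InterfaceError("both complexes need enumerated copies")
    ref_copy, mod_copy = reference.copies[0], model.copies[0]
    ref_e2 = reference.chain(ref_copy.e2_chain)
    mod_e2 = model.chain(mod_copy.e2_chain)

    def helix_for(complex, copy, chain):
        entry = None
        if refs is not None and chain.role is not None and chain.role.gene:
            entry = refs.e2_registry.get(chain.role.gene)
        return find_crossover_helix(chain, registry_entry=entry)

    ref_helix = helix_for(reference, ref_copy, ref_e2)
    mod_helix = helix_for(model, mod_copy, mod_e2)
    common = sorted(
        set(range(ref_helix.start, ref_helix.end + 1))
        & set(range(mod_helix.start, mod_helix.end + 1))
    )
    ref_anchor, mod_anchor = [], []
    for num in common:
        r1 = ref_e2.residue_by_number(num)
        r2 = mod_e2.residue_by_number(num)
        if r1 is not None and r2 is not None and r1.ca is not None and r2.ca is not None:
            ref_anchor.append(r1.ca)
            mod_anchor.append(r2.ca)
    if len(ref_anchor) < 3:
        raise InterfaceError(
            f"only {len(ref_anchor)} paired crossover-helix residues; need >= 3 for superposition"
        )
    sup = SVDSuperimposer()
    sup.set(np.asarray(ref_anchor), np.asarray(mod_anchor))
    sup.run()
    rot, tran = sup.get_rotran()

    def ca_map(complex, copy):
        out = {}
        for role in (Role.UBIQUITIN, Role.E2, Role.E3):
            chain = _role_chain(complex, copy, role)
            if chain is None:
                continue
            for res in chain.residues:
                if res.ca is not None:
                    out[_role_residue_key(chain, res.number, role)] = res.ca
        return out

    ref_cas = ca_map(reference, ref_copy)
    mod_cas = {k: (v @ rot + tran) for k, v in ca_map(model, mod_copy).items()}

    pair_roles = {"UB-E2": (Role.UBIQUITIN, Role.E2),
                  "UB-E3": (Role.UBIQUITIN, Role.E3),
                  "E2-E3": (Role.E2, Role.E3)}

    def iface_keys(complex, copy, pair):
        role_a, role_b = pair_roles[pair]
        ca = _role_chain(complex, copy, role_a)
        cb = _role_chain(complex, copy, role_b)
        if ca is None or cb is None:
            return None
        iface = interface_residues(ca, cb, pair, cutoff)
        keys = set()
        for cid, num in iface.residues:
            chain = complex.chain(cid)
            role = role_a if cid == ca.chain_id else role_b
            keys.add(_role_residue_key(chain, num, role))
        return keys

    per_interface: dict[str, float] = {}
    all_sq: list[float] = []
    n_common = 0
    for pair in INTERFACE_NAMES:
        ref_keys = iface_keys(reference, ref_copy, pair)
        mod_keys = iface_keys(model, mod_copy, pair)
        if ref_keys is None or mod_keys is None:
            continue
        keys = (ref_keys | mod_keys) & set(ref_cas) & set(mod_cas)
        if not keys:
            continue
        sq = [float(np.sum((ref_cas[k] - mod_cas[k]) ** 2)) for k in sorted(keys)]
        per_interface[pair] = float(np.sqrt(np.mean(sq)))
        all_sq.extend(sq)
        n_common += len(keys)
    if not all_sq:
        raise InterfaceError("no common interface residues between reference and model")
    return InterfaceRMSDResult(per_interface, float(np.sqrt(np.mean(all_sq))), n_common)
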