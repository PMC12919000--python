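"""Coordinate model for ubiquitin-E2-E3 complexes.

Reads PDB/mmCIF files into a light-weight chain/residue/atom hierarchy,
assigns chain roles by sequence identity against a reference registry, and
groups chains into ternary-complex copies (one ubiquitin + one E2 + optionally
one E3 per copy).

Author residue numbering is the canonical coordinate system throughout.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as _pdb_io
import biotite.structure.io.pdbx as _pdbx_io
from Bio.Align import PairwiseAligner

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "ChainRole",
    "Role",
    "Copy",
    "TernaryComplex",
    "E2Entry",
    "E3Entry",
    "ReferenceSequences",
    "StructureError",
    "EmptyStructureError",
    "AmbiguousRoleError",
    "load_structure",
    "write_structure",
    "load_registry",
    "write_registry",
    "assign_roles",
    "enumerate_copies",
    "sequence_identity",
]

# Maximum centroid distance for a ubiquitin chain to be grouped with an E2.
ORPHAN_CUTOFF = 60.0

_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
_1TO3 = {v: k for k, v in reversed(list(_3TO1.items()))}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Base class for structure-model errors."""


class EmptyStructureError(StructureError):
    """Raised when a file contains no protein chains."""


class AmbiguousRoleError(StructureError):
    """Raised when several chains claim the same single-slot role."""


class Role(str, Enum):
    UBIQUITIN = "UBIQUITIN"
    E2 = "E2"
    E3 = "E3"
    OTHER = "OTHER"


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise StructureError(
                f"non-finite or malformed coordinates for atom "
                f"{self.chain_id}/{self.residue_number}/{self.atom_name}"
            )
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return _3TO1.get(self.name.upper(), "X")

    @property
    def ca(self) -> Optional[np.ndarray]:
        atom = self.atoms.get("CA")
        return None if atom is None else atom.coords

    def atom_coords(self, name: str) -> Optional[np.ndarray]:
        atom = self.atoms.get(name)
        return None if atom is None else atom.coords

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms.values() if a.element != "H"]
        return np.asarray(coords) if coords else np.empty((0, 3))

    def polar_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms.values() if a.element in ("N", "O")]


@dataclass
class ChainRole:
    role: Role
    evidence: str = ""
    identity_fraction: float = 0.0
    gene: Optional[str] = None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    role: Optional[ChainRole] = None
    # canonical ubiquitin position (1..76) -> Residue, set for UBIQUITIN chains
    ub_map: Optional[dict[int, Residue]] = None

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_number(self, number: int, icode: str = "") -> Optional[Residue]:
        for res in self.residues:
            if res.number == number and res.insertion_code == icode:
                return res
        return None

    def ca_array(self) -> tuple[list[Residue], np.ndarray]:
        """Residues that have a CA atom, with their CA coordinates."""
        residues = [r for r in self.residues if r.ca is not None]
        coords = np.asarray([r.ca for r in residues]) if residues else np.empty((0, 3))
        return residues, coords

    def centroid(self) -> np.ndarray:
        _, coords = self.ca_array()
        if len(coords) == 0:
            coords = np.concatenate(
                [r.heavy_coords() for r in self.residues if len(r.heavy_coords())]
            )
        return coords.mean(axis=0)

    def ub_residue(self, canonical: int) -> Optional[Residue]:
        """Residue at a canonical ubiquitin position (author map aware)."""
        if self.ub_map is not None:
            return self.ub_map.get(canonical)
        return self.residue_by_number(canonical)

    def atoms(self) -> Iterable[AtomRecord]:
        for res in self.residues:
            yield from res.atoms.values()


@dataclass(frozen=True)
class Copy:
    ub_chain: str
    e2_chain: str
    e3_chain: Optional[str] = None


@dataclass
class TernaryComplex:
    complex_id: str
    chains: dict[str, Chain]
    copies: list[Copy] = field(default_factory=list)
    source: str = "experimental"
    warnings: list[str] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        return self.chains[chain_id]

    def chains_with_role(self, role: Role) -> list[Chain]:
        return [c for c in self.chains.values() if c.role and c.role.role == role]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TernaryComplex":
        """Return a rigid-transformed copy of the whole complex."""
        new_chains = {}
        for cid, chain in self.chains.items():
            residues = []
            for res in chain.residues:
                atoms = {
                    name: dataclasses.replace(a, coords=rotation @ a.coords + translation)
                    for name, a in res.atoms.items()
                }
                residues.append(Residue(res.number, res.insertion_code, res.name, atoms))
            new_chain = Chain(cid, residues, role=chain.role)
            if chain.ub_map is not None:
                by_key = {r.key: r for r in residues}
                new_chain.ub_map = {
                    pos: by_key[res.key] for pos, res in chain.ub_map.items()
                }
            new_chains[cid] = new_chain
        return TernaryComplex(
            self.complex_id, new_chains, list(self.copies), self.source, list(self.warnings)
        )


# ---------------------------------------------------------------------------
# Reference registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class E2Entry:
    gene: str
    sequence: str
    catalytic_cys: Optional[int]  # author residue number; None for UBE2V-type
    helix_span: Optional[tuple[int, int]] = None
    binding_loop: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.catalytic_cys is not None:
            pos = self.catalytic_cys
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "C":
                raise ValueError(
                    f"catalytic cysteine of {self.gene} at {pos} does not point to C"
                )


@dataclass(frozen=True)
class E3Entry:
    gene: str
    sequence: str
    domains: tuple = ()


@dataclass
class ReferenceSequences:
    ubiquitin_seq: str
    e2_registry: dict[str, E2Entry] = field(default_factory=dict)
    e3_registry: dict[str, E3Entry] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ubiquitin_seq) != 76:
            raise ValueError("ubiquitin reference sequence must have 76 residues")


# Canonical human ubiquitin (UBB monomer unit).
UBIQUITIN_SEQ = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

_REGISTRY_HEADER = ["gene", "kind", "sequence", "catalytic_cys", "helix_start", "helix_end"]


def load_registry(path) -> ReferenceSequences:
    """Read a reference registry TSV (gene, kind, sequence, catalytic_cys,
    helix_start, helix_end). kind is one of UB / E2 / E3; empty numeric fields
    are allowed."""
    ub_seq = None
    e2s: dict[str, E2Entry] = {}
    e3s: dict[str, E3Entry] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in header}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")

            def get(col):
                i = idx.get(col)
                if i is None or i >= len(parts):
                    return ""
                return parts[i].strip()

            kind = get("kind").upper()
            gene = get("gene")
            seq = get("sequence")
            if kind == "UB":
                ub_seq = seq
            elif kind == "E2":
                cys = int(get("catalytic_cys")) if get("catalytic_cys") else None
                hs, he = get("helix_start"), get("helix_end")
                span = (int(hs), int(he)) if hs and he else None
                e2s[gene] = E2Entry(gene, seq, cys, span)
            elif kind == "E3":
                e3s[gene] = E3Entry(gene, seq)
    if ub_seq is None:
        ub_seq = UBIQUITIN_SEQ
    return ReferenceSequences(ub_seq, e2s, e3s)


def write_registry(refs: ReferenceSequences, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REGISTRY_HEADER) + "\n")
        fh.write(f"UB\tUB\t{refs.ubiquitin_seq}\t\t\t\n")
        for e2 in refs.e2_registry.values():
            cys = "" if e2.catalytic_cys is None else str(e2.catalytic_cys)
            hs = he = ""
            if e2.helix_span is not None:
                hs, he = str(e2.helix_span[0]), str(e2.helix_span[1])
            fh.write(f"{e2.gene}\tE2\t{e2.sequence}\t{cys}\t{hs}\t{he}\n")
        for e3 in refs.e3_registry.values():
            fh.write(f"{e3.gene}\tE3\t{e3.sequence}\t\t\t\n")


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    with open(path) as fh:
        head = fh.read(2048)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _atom_array(path: Path, fmt: str) -> bst.AtomArray:
    try:
        if fmt == "pdb":
            pdb_file = _pdb_io.PDBFile.read(str(path))
            arr = pdb_file.get_structure(
                model=1, altloc="occupancy", extra_fields=["occupancy"]
            )
        else:
            cif_file = _pdbx_io.CIFFile.read(str(path))
            arr = _pdbx_io.get_structure(
                cif_file, model=1, altloc="occupancy", extra_fields=["occupancy"],
                use_author_fields=True,
            )
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise StructureError(f"could not parse {path} as {fmt}: {exc}") from exc
    return arr


def load_structure(path, fmt: str = "auto", complex_id: Optional[str] = None,
                   source: str = "experimental") -> TernaryComplex:
    """Load a PDB/mmCIF file into a :class:`TernaryComplex` with roles unassigned.

    Alternate locations are collapsed to the highest-occupancy conformer and
    waters are excluded.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise StructureError(f"unknown format {fmt!r}")
    arr = _atom_array(path, fmt)

    chains: dict[str, Chain] = {}
    for i in range(arr.array_length()):
        res_name = arr.res_name[i]
        if res_name in _WATER_NAMES:
            continue
        cid = str(arr.chain_id[i])
        chain = chains.setdefault(cid, Chain(cid))
        icode = str(arr.ins_code[i]) if "ins_code" in arr.get_annotation_categories() else ""
        key = (int(arr.res_id[i]), icode)
        if not chain.residues or chain.residues[-1].key != key:
            existing = next((r for r in chain.residues if r.key == key), None)
            if existing is None:
                chain.residues.append(Residue(key[0], key[1], str(res_name)))
        res = next(r for r in chain.residues if r.key == key)
        occ = float(arr.occupancy[i]) if "occupancy" in arr.get_annotation_categories() else 1.0
        record = AtomRecord(
            chain_id=cid,
            residue_number=key[0],
            insertion_code=key[1],
            residue_name=str(res_name),
            atom_name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            coords=np.array(arr.coord[i], dtype=float),
            occupancy=occ,
            is_hetero=bool(arr.hetero[i]),
        )
        res.atoms[record.atom_name] = record

    chains = {cid: c for cid, c in chains.items()
              if any(r.name.upper() in _3TO1 for r in c.residues)}
    if not chains:
        raise EmptyStructureError(f"{path} contains no protein chains")
    return TernaryComplex(complex_id or path.stem, chains, source=source)


def write_structure(complex: TernaryComplex, path, fmt: str = "auto") -> None:
    """Serialize a complex back to PDB or mmCIF."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif", ".pdbx") else "pdb"
    records = [a for chain in complex.chains.values() for a in chain.atoms()]
    n = len(records)
    arr = bst.AtomArray(n)
    arr.add_annotation("occupancy", dtype=float)
    for i, rec in enumerate(records):
        arr.chain_id[i] = rec.chain_id
        arr.res_id[i] = rec.residue_number
        arr.ins_code[i] = rec.insertion_code
        arr.res_name[i] = rec.residue_name
        arr.atom_name[i] = rec.atom_name
        arr.element[i] = rec.element
        arr.hetero[i] = rec.is_hetero
        arr.occupancy[i] = rec.occupancy
        arr.coord[i] = rec.coords
    if fmt == "pdb":
        pdb_file = _pdb_io.PDBFile()
        pdb_file.set_structure(arr)
        pdb_file.write(str(path))
    else:
        cif_file = _pdbx_io.CIFFile()
        _pdbx_io.set_structure(cif_file, arr, data_block=complex.complex_id or "model")
        cif_file.write(str(path))


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_identity(query: str, reference: str) -> tuple[float, int, list[tuple[int, int]]]:
    """Local-alignment identity between two sequences.

    Returns (identity over aligned columns, number of aligned columns,
    list of (query_index, reference_index) aligned pairs; 0-based).
    """
    if not query or not reference:
        return 0.0, 0, []
    aligner = _make_aligner()
    try:
        aln = aligner.align(query, reference)[0]
    except (IndexError, ValueError):
        return 0.0, 0, []
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for qi, ri in zip(range(qs, qe), range(rs, re_)):
            pairs.append((qi, ri))
            if query[qi] == reference[ri]:
                matches += 1
    if not pairs:
        return 0.0, 0, []
    return matches / len(pairs), len(pairs), pairs


def _best_registry_hit(seq: str, registry: Mapping[str, object]) -> tuple[Optional[str], float]:
    best_gene, best_identity = None, 0.0
    for gene, entry in registry.items():
        identity, n_aligned, _ = sequence_identity(seq, entry.sequence)
        # weight by coverage so that a tiny perfect local hit does not win
        coverage = n_aligned / max(len(entry.sequence), 1)
        score = identity if coverage >= 0.5 else identity * coverage
        if score > best_identity:
            best_gene, best_identity = gene, score
    return best_gene, best_identity


def assign_roles(complex: TernaryComplex, refs: ReferenceSequences,
                 overrides: Optional[Mapping[str, Role | str]] = None) -> TernaryComplex:
    """Tag every chain with a role based on registry sequence identity.

    UBIQUITIN requires >= 90% identity over >= 70 aligned residues; E2 and E3
    require >= 60% identity against their registries. Explicit overrides win.
    """
    overrides = {k: Role(v) for k, v in (overrides or {}).items()}
    for cid, chain in complex.chains.items():
        if cid in overrides:
            chain.role = ChainRole(overrides[cid], evidence="override", identity_fraction=1.0)
            if overrides[cid] == Role.UBIQUITIN:
                _set_ub_map(chain, refs.ubiquitin_seq)
            continue
        seq = chain.sequence
        ub_identity, ub_aligned, _ = sequence_identity(seq, refs.ubiquitin_seq)
        if ub_identity >= 0.90 and ub_aligned >= 70:
            chain.role = ChainRole(Role.UBIQUITIN, evidence="ubiquitin-identity",
                                   identity_fraction=ub_identity)
            _set_ub_map(chain, refs.ubiquitin_seq)
            continue
        e2_gene, e2_identity = _best_registry_hit(seq, refs.e2_registry)
        if e2_gene is not None and e2_identity >= 0.60:
            chain.role = ChainRole(Role.E2, evidence=f"registry:{e2_gene}",
                                   identity_fraction=e2_identity, gene=e2_gene)
            continue
        e3_gene, e3_identity = _best_registry_hit(seq, refs.e3_registry)
        if e3_gene is not None and e3_identity >= 0.60:
            chain.role = ChainRole(Role.E3, evidence=f"registry:{e3_gene}",
                                   identity_fraction=e3_identity, gene=e3_gene)
            continue
        chain.role = ChainRole(Role.OTHER, evidence="no-registry-hit", identity_fraction=0.0)
    return complex


def _set_ub_map(chain: Chain, ub_seq: str) -> None:
    """Map canonical ubiquitin positions 1..76 onto chain residues.

    Fusion chains longer than ubiquitin are implicitly truncated to the
    best-matching window via local alignment.
    """
    _, _, pairs = sequence_identity(chain.sequence, ub_seq)
    chain.ub_map = {ri + 1: chain.residues[qi] for qi, ri in pairs}
    if len(chain.residues) > len(ub_seq):
        pass  # truncation to the aligned window is what ub_map encodes


# ---------------------------------------------------------------------------
# Copy enumeration
# ---------------------------------------------------------------------------

def enumerate_copies(complex: TernaryComplex,
                     max_pair_dist: float = ORPHAN_CUTOFF) -> TernaryComplex:
    """Group chains into ternary copies by greedy nearest-centroid matching.

    Each ubiquitin chain is paired with its closest unused E2 (within
    ``max_pair_dist`` of the centroid), then with the closest unused E3 when
    one exists. Ubiquitin chains with no E2 in range are excluded with a
    warning.
    """
    ubs = complex.chains_with_role(Role.UBIQUITIN)
    e2s = {c.chain_id: c.centroid() for c in complex.chains_with_role(Role.E2)}
    e3s = {c.chain_id: c.centroid() for c in complex.chains_with_role(Role.E3)}
    copies: list[Copy] = []
    used_e2: set[str] = set()
    used_e3: set[str] = set()
    # deterministic: closest UB-E2 pairs first
    candidates = []
    for ub in ubs:
        ub_centroid = ub.centroid()
        for e2_id, e2_centroid in e2s.items():
            dist = float(np.linalg.norm(ub_centroid - e2_centroid))
            if dist <= max_pair_dist:
                candidates.append((dist, ub.chain_id, e2_id))
    candidates.sort()
    paired_ub: set[str] = set()
    for dist, ub_id, e2_id in candidates:
        if ub_id in paired_ub or e2_id in used_e2:
            continue
        paired_ub.add(ub_id)
        used_e2.add(e2_id)
        e3_id = None
        if e3s:
            pair_centroid = (complex.chain(ub_id).centroid() + complex.chain(e2_id).centroid()) / 2
            options = sorted(
                (float(np.linalg.norm(pair_centroid - c)), cid)
                for cid, c in e3s.items() if cid not in used_e3
            )
            if options and options[0][0] <= max_pair_dist:
                e3_id = options[0][1]
                used_e3.add(e3_id)
        copies.append(Copy(ub_id, e2_id, e3_id))
    for ub in ubs:
        if ub.chain_id not in paired_ub:
            complex.warnings.append(
                f"orphan ubiquitin chain {ub.chain_id}: no E2 within {max_pair_dist} A"
            )
    slot_check: dict[str, list[str]] = {}
    for copy in copies:
        slot_check.setdefault(copy.e2_chain, []).append(copy.ub_chain)
    complex.copies = sorted(copies, key=lambda c: (c.ub_chain, c.e2_chain))
    return complex
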