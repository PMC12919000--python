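"""Synthetic fixtures with controllable ground truth.

Generates every input the pipeline consumes without any downloads:

* toy ternary-complex coordinates (ideal-geometry backbone chains) with
  tunable Ile44-helix and tail-cysteine distances, optional planted linchpin
  bridge, and rigid-body asymmetric-unit replicas;
* prediction-confidence JSON files in both supported dialects;
* interface-energetics tables;
* physical-interaction edge tables with planted scored edges;
* labeled feature tables with planted pair / non-pair effect directions.

Every generator is deterministic under its seed and emits a manifest
sufficient to verify downstream calls without re-deriving geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import confidence_scores as conf_mod
from .energetics_ingest import ENERGETICS_COLUMNS, EnergeticsRecord
from .pair_classifier import COMPLEX_FEATURES, FEATURE_COLUMNS, INTERFACE_PREFIXES
from .structure_model import (
    _1TO3,
    UBIQUITIN_SEQ,
    AtomRecord,
    Chain,
    ChainRole,
    Copy,
    E2Entry,
    E3Entry,
    ReferenceSequences,
    Residue,
    Role,
    TernaryComplex,
)

__all__ = [
    "ComplexSpec",
    "FeatureTableSpec",
    "toy_registry",
    "make_complex",
    "make_confidence",
    "make_edge_table",
    "make_energetics_table",
    "make_feature_table",
]

# E2 chain layout (author numbering)
E2_LEN = 40
E2_STRAND = (1, 12)
E2_LOOP = (13, 22)
E2_CYS = 18
E2_HELIX = (23, 38)
E3_LEN = 30
E3_LOOP = (10, 14)
E3_ARG = 12

HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
HELIX_RADIUS = 2.3

COPY_SPACING = 250.0

_N_OFF = np.array([0.5, 0.5, 0.3])
_C_OFF = np.array([-0.5, -0.5, 0.3])
_O_OFF = np.array([-0.5, 0.5, -0.3])


class ConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class ComplexSpec:
    conformation: str = "closed"            # "closed" | "open"
    ile44_target_dist: float = 7.0
    tail_target_dist: float = 4.0
    with_linchpin: bool = True
    n_copies: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.ile44_target_dist <= 0 or self.tail_target_dist <= 0:
            raise ConstructionError("target distances must be positive")
        if self.conformation == "closed" and (
                self.ile44_target_dist >= 10.0 or self.tail_target_dist >= 12.0):
            raise ConstructionError("closed spec requires targets below the cutoffs")
        if self.n_copies < 1:
            raise ConstructionError("n_copies must be >= 1")


def _toy_seq(length: int, special: dict[int, str], stride: int = 7, phase: int = 3) -> str:
    # deterministic C-free filler so the only cysteines are the planted ones;
    # distinct (stride, phase) keep the toy E2 and E3 sequences dissimilar
    alphabet = "ADEFGHIKLMNPQRSTVWY"
    seq = [alphabet[(stride * i + phase) % len(alphabet)] for i in range(length)]
    for pos, letter in special.items():
        seq[pos - 1] = letter
    return "".join(seq)


E2_TOY_SEQ = _toy_seq(E2_LEN, {E2_CYS: "C"}, stride=7, phase=3)
E3_TOY_SEQ = _toy_seq(E3_LEN, {E3_ARG: "R"}, stride=11, phase=5)


def toy_registry(include_cysless_e2: bool = False) -> ReferenceSequences:
    """Registry matching the toy chains emitted by :func:`make_complex`."""
    e2s = {
        "E2TOY": E2Entry("E2TOY", E2_TOY_SEQ, E2_CYS, E2_HELIX),
    }
    if include_cysless_e2:
        # UBE2V-style E2: same fold, no catalytic cysteine
        seq = _toy_seq(E2_LEN, {E2_CYS: "S"})
        e2s["E2VTOY"] = E2Entry("E2VTOY", seq, None, E2_HELIX)
    return ReferenceSequences(
        UBIQUITIN_SEQ,
        e2s,
        {"E3TOY": E3Entry("E3TOY", E3_TOY_SEQ)},
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _helix_ca(k: int) -> np.ndarray:
    theta = math.radians(HELIX_TURN_DEG * k)
    return np.array([
        HELIX_RISE * k,
        HELIX_RADIUS * math.cos(theta),
        HELIX_RADIUS * math.sin(theta),
    ])


def _helix_radial(k: int) -> np.ndarray:
    theta = math.radians(HELIX_TURN_DEG * k)
    return np.array([0.0, math.cos(theta), math.sin(theta)])


def _residue(chain_id: str, number: int, one_letter: str, ca: np.ndarray,
             extra: Optional[dict[str, np.ndarray]] = None,
             atom_offsets: bool = True) -> Residue:
    name = _1TO3.get(one_letter, "GLY")
    atoms: dict[str, AtomRecord] = {}

    def add(atom_name: str, element: str, coords: np.ndarray):
        atoms[atom_name] = AtomRecord(chain_id, number, "", name, atom_name,
                                      element, np.asarray(coords, dtype=float))

    add("CA", "C", ca)
    if atom_offsets:
        add("N", "N", ca + _N_OFF)
        add("C", "C", ca + _C_OFF)
        add("O", "O", ca + _O_OFF)
    for atom_name, coords in (extra or {}).items():
        element = "N" if atom_name.startswith("N") else ("O" if atom_name.startswith("O") else "C")
        add(atom_name, element, coords)
    return Residue(number, "", name, atoms)


def _build_e2(chain_id: str) -> Chain:
    residues = []
    for i in range(E2_STRAND[0], E2_STRAND[1] + 1):
        ca = np.array([-28.0 + 3.4 * (i - E2_STRAND[1]), 12.0, 0.0])
        residues.append(_residue(chain_id, i, E2_TOY_SEQ[i - 1], ca))
    for i in range(E2_LOOP[0], E2_LOOP[1] + 1):
        ca = np.array([2.8 * (i - E2_HELIX[0]), 6.0 + 1.2 * ((-1) ** i), 0.0])
        residues.append(_residue(chain_id, i, E2_TOY_SEQ[i - 1], ca))
    for i in range(E2_HELIX[0], E2_HELIX[1] + 1):
        residues.append(_residue(chain_id, i, E2_TOY_SEQ[i - 1], _helix_ca(i - E2_HELIX[0])))
    for i in range(E2_HELIX[1] + 1, E2_LEN + 1):
        ca = np.array([24.0 + 3.0 * (i - E2_HELIX[1]), 9.0, -3.0])
        residues.append(_residue(chain_id, i, E2_TOY_SEQ[i - 1], ca))
    return Chain(chain_id, residues)


def _build_e3(chain_id: str, spec: ComplexSpec,
              tail_o: Optional[np.ndarray], e2_o: Optional[np.ndarray]) -> Chain:
    residues = []
    for i in range(1, E3_LOOP[0]):
        ca = np.array([-24.0 - 3.4 * (E3_LOOP[0] - i), 6.6, 8.5])
        residues.append(_residue(chain_id, i, E3_TOY_SEQ[i - 1], ca))
    for i in range(E3_LOOP[0], E3_LOOP[1] + 1):
        ca = np.array([-24.0 + 3.0 * (i - E3_LOOP[0]), 6.6, 6.0 + 0.7 * ((-1) ** i)])
        extra = {}
        if i == E3_ARG:
            if spec.with_linchpin and tail_o is not None and e2_o is not None:
                for atom_name, target in (("NH1", tail_o), ("NH2", e2_o)):
                    direction = ca - target
                    direction = direction / np.linalg.norm(direction)
                    extra[atom_name] = target + 3.0 * direction
            else:
                extra["NH1"] = ca + np.array([0.0, 0.0, 3.0])
                extra["NH2"] = ca + np.array([0.0, 1.0, 2.8])
        residues.append(_residue(chain_id, i, E3_TOY_SEQ[i - 1], ca, extra=extra))
    for i in range(E3_LOOP[1] + 1, E3_LEN + 1):
        ca = np.array([-12.0 + 3.4 * (i - E3_LOOP[1]), 6.6, 8.5])
        residues.append(_residue(chain_id, i, E3_TOY_SEQ[i - 1], ca))
    return Chain(chain_id, residues)


def _build_ub(chain_id: str, spec: ComplexSpec,
              cys_ca: np.ndarray) -> tuple[Chain, np.ndarray, np.ndarray]:
    """Ubiquitin stand-in. Returns (chain, q44, tail-O for linchpin)."""
    d1 = spec.ile44_target_dist
    d2 = spec.tail_target_dist
    # helix residue whose radial direction points away from the E2 loop (-y)
    anchor_k = 2
    q44 = _helix_ca(anchor_k) + d1 * _helix_radial(anchor_k)
    q76 = cys_ca + d2 * np.array([0.0, 0.0, -1.0])

    residues: dict[int, Residue] = {}
    # compact body grid for residues 1..70 except 44
    body = [i for i in range(1, 71) if i != 44]
    for slot, i in enumerate(body):
        ca = np.array([3.2 * (slot % 15), -16.0 - 4.5 * (slot // 15), 0.0])
        residues[i] = _residue(chain_id, i, UBIQUITIN_SEQ[i - 1], ca)
    residues[44] = _residue(chain_id, 44, UBIQUITIN_SEQ[43], q44)
    # C-terminal tail 71..76, ending with the residue-76 carbonyl carbon at q76
    tail_dir = np.array([-1.0, 0.0, -0.35])
    tail_dir = tail_dir / np.linalg.norm(tail_dir)
    ca76 = q76 + np.array([0.0, 0.5, -1.2])
    tail_o_for_linchpin = None
    for i in range(71, 77):
        ca = ca76 + (76 - i) * 3.3 * tail_dir
        res = _residue(chain_id, i, UBIQUITIN_SEQ[i - 1], ca)
        if i == 76:
            # exact carbonyl placement overrides the offset-based C and O
            res.atoms["C"] = AtomRecord(chain_id, i, "", res.name, "C", "C", q76)
            res.atoms["O"] = AtomRecord(chain_id, i, "", res.name, "O", "O",
                                        q76 + np.array([0.0, 0.0, -0.6]))
        if i == 74:
            tail_o_for_linchpin = res.atoms["O"].coords
        residues[i] = res
    chain = Chain(chain_id, [residues[i] for i in sorted(residues)])
    return chain, q44, tail_o_for_linchpin


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def make_complex(spec: ComplexSpec, out_dir: Optional[Path] = None,
                 complex_id: str = "toy", include_e3: bool = True,
                 assign: bool = True) -> tuple[TernaryComplex, dict]:
    """Build a toy ternary complex realizing the spec's target geometry.

    Returns the in-memory complex (roles assigned and copies enumerated when
    ``assign``) and a ground-truth manifest. When ``out_dir`` is given, the
    structure is written as both PDB and mmCIF alongside the manifest.
    """
    if spec.conformation == "open" and (
            spec.ile44_target_dist < 10.0 and spec.tail_target_dist < 12.0):
        raise ConstructionError("open spec requires at least one target beyond its cutoff")
    chains: dict[str, Chain] = {}
    copies: list[Copy] = []
    per_copy_chains = 3 if include_e3 else 2
    for copy_idx in range(spec.n_copies):
        shift = np.array([0.0, COPY_SPACING * copy_idx, COPY_SPACING * copy_idx])
        ids = _CHAIN_IDS[copy_idx * per_copy_chains:(copy_idx + 1) * per_copy_chains]
        ub_id, e2_id = ids[0], ids[1]
        e3_id = ids[2] if include_e3 else None
        e2 = _build_e2(e2_id)
        cys_ca = e2.residue_by_number(E2_CYS).ca
        ub, q44, tail_o = _build_ub(ub_id, spec, cys_ca)
        built = [ub, e2]
        if include_e3:
            e2_o = e2.residue_by_number(16).atoms["O"].coords
            built.append(_build_e3(e3_id, spec, tail_o, e2_o))
        for chain in built:
            for res in chain.residues:
                for name, atom in list(res.atoms.items()):
                    res.atoms[name] = AtomRecord(
                        atom.chain_id, atom.residue_number, atom.insertion_code,
                        atom.residue_name, atom.atom_name, atom.element,
                        atom.coords + shift, atom.occupancy, atom.is_hetero,
                    )
            chains[chain.chain_id] = chain
        copies.append(Copy(ub_id, e2_id, e3_id))
    complex = TernaryComplex(complex_id, chains, source="predicted")
    if assign:
        for copy in copies:
            complex.chain(copy.ub_chain).role = ChainRole(Role.UBIQUITIN, "synthetic", 1.0)
            complex.chain(copy.ub_chain).ub_map = {
                i: complex.chain(copy.ub_chain).residue_by_number(i) for i in range(1, 77)
            }
            complex.chain(copy.e2_chain).role = ChainRole(Role.E2, "synthetic", 1.0, gene="E2TOY")
            if copy.e3_chain:
                complex.chain(copy.e3_chain).role = ChainRole(Role.E3, "synthetic", 1.0, gene="E3TOY")
        complex.copies = copies
    manifest = {
        "complex_id": complex_id,
        "conformation": spec.conformation,
        "ile44_target_dist": spec.ile44_target_dist,
        "tail_target_dist": spec.tail_target_dist,
        "with_linchpin": spec.with_linchpin and include_e3,
        "n_copies": spec.n_copies,
        "copies": [[c.ub_chain, c.e2_chain, c.e3_chain] for c in copies],
        "e2_helix": list(E2_HELIX),
        "e2_cys": E2_CYS,
        "linchpin_residue": E3_ARG if (spec.with_linchpin and include_e3) else None,
    }
    if out_dir is not None:
        from .structure_model import write_structure

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_structure(complex, out_dir / f"{complex_id}.pdb", fmt="pdb")
        write_structure(complex, out_dir / f"{complex_id}.cif", fmt="mmcif")
        (out_dir / f"{complex_id}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return complex, manifest


# ---------------------------------------------------------------------------
# Confidence files
# ---------------------------------------------------------------------------

def make_confidence(chain_sizes: Sequence[int], interface_error: float,
                    background_error: float, seed: int = 0,
                    chain_ids: Optional[Sequence[str]] = None,
                    out_dir: Optional[Path] = None,
                    stem: str = "toy") -> tuple[conf_mod.PredictionConfidence, dict]:
    """Synthetic PAE/pLDDT/ipTM with block structure.

    Within-chain PAE blocks sit at an attenuated background level; inter-chain
    blocks center on ``interface_error`` with jitter proportional to the
    error, so a zero-error spec yields an exactly-zero matrix. pLDDT is
    anticorrelated with each residue's mean inter-chain PAE, and chain-pair
    ipTM is computed consistently from the generated matrix.
    """
    if interface_error < 0 or background_error < 0:
        raise ValueError("errors must be non-negative")
    chain_ids = list(chain_ids or _CHAIN_IDS[:len(chain_sizes)])
    rng = np.random.default_rng(seed)
    n = int(sum(chain_sizes))
    spans = {}
    offset = 0
    for cid, size in zip(chain_ids, chain_sizes):
        spans[cid] = (offset, offset + int(size))
        offset += int(size)
    pae = np.zeros((n, n))
    for ci, (si, ei) in spans.items():
        for cj, (sj, ej) in spans.items():
            shape = (ei - si, ej - sj)
            if ci == cj:
                level = background_error * 0.25
            else:
                level = interface_error
            jitter = 0.05 * level * rng.uniform(-1.0, 1.0, size=shape)
            pae[si:ei, sj:ej] = np.clip(level + jitter, 0.0, None)
    inter_mask = np.ones((n, n), dtype=bool)
    for si, ei in spans.values():
        inter_mask[si:ei, si:ei] = False
    if inter_mask.any():
        per_res = np.array([
            pae[i, inter_mask[i]].mean() if inter_mask[i].any() else 0.0 for i in range(n)
        ])
    else:
        per_res = np.zeros(n)
    plddt = np.clip(95.0 - 2.5 * per_res, 0.0, 100.0)
    conf = conf_mod.PredictionConfidence(plddt, pae, spans)
    pair_iptm = {}
    for i, ci in enumerate(chain_ids):
        for cj in chain_ids[i + 1:]:
            value = conf_mod.interface_iptm(conf, (ci, cj))
            pair_iptm[(ci, cj)] = value
            pair_iptm[(cj, ci)] = value
    conf.chain_pair_iptm = dict(pair_iptm)
    manifest = {
        "chain_ids": chain_ids,
        "chain_sizes": [int(s) for s in chain_sizes],
        "interface_error": interface_error,
        "background_error": background_error,
        "seed": seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        token_chain_ids = [cid for cid, size in zip(chain_ids, chain_sizes)
                           for _ in range(int(size))]
        token_res_ids = [r + 1 for size in chain_sizes for r in range(int(size))]
        af3 = {
            "pae": pae.tolist(),
            "plddt": plddt.tolist(),
            "token_chain_ids": token_chain_ids,
            "token_res_ids": token_res_ids,
            "chain_ids": chain_ids,
            "chain_pair_iptm": [
                [0.0 if ci == cj else pair_iptm[(ci, cj)] for cj in chain_ids]
                for ci in chain_ids
            ],
        }
        (out_dir / f"{stem}.af3.json").write_text(json.dumps(af3))
        colabfold = {"pae": pae.tolist(), "plddt": plddt.tolist()}
        (out_dir / f"{stem}.colabfold.json").write_text(json.dumps(colabfold))
        (out_dir / f"{stem}.confidence_manifest.json").write_text(json.dumps(manifest, indent=2))
    return conf, manifest


# ---------------------------------------------------------------------------
# Edge tables
# ---------------------------------------------------------------------------

def make_edge_table(n_e2: int, n_e3: int, n_true_edges: int, seed: int = 0,
                    n_low_edges: int = 0, n_nonexp_edges: int = 0,
                    out_dir: Optional[Path] = None,
                    stem: str = "edges") -> tuple[pd.DataFrame, dict]:
    """Edge TSV with planted qualifying edges (experimental score >= 400),
    sub-threshold experimental edges, and non-experimental-evidence edges.
    All planted combinations are distinct."""
    total = n_true_edges + n_low_edges + n_nonexp_edges
    if total > n_e2 * n_e3:
        raise ValueError("more planted edges than available combinations")
    e2s = [f"E2_{i:03d}" for i in range(1, n_e2 + 1)]
    e3s = [f"E3_{i:03d}" for i in range(1, n_e3 + 1)]
    rng = np.random.default_rng(seed)
    combos = [(a, b) for a in e2s for b in e3s]
    picked = rng.choice(len(combos), size=total, replace=False)
    rows = []
    true_edges, low_edges, nonexp_edges = [], [], []
    for rank, idx in enumerate(picked):
        e2, e3 = combos[idx]
        if rank < n_true_edges:
            score = int(rng.integers(400, 951))
            true_edges.append([e2, e3, score])
        elif rank < n_true_edges + n_low_edges:
            score = int(rng.integers(50, 400))
            low_edges.append([e2, e3, score])
        else:
            score = 0
            nonexp_edges.append([e2, e3])
        combined = max(score, int(rng.integers(150, 500))) if score == 0 else score
        # randomize direction to exercise deduplication
        a, b = (e2, e3) if rng.random() < 0.5 else (e3, e2)
        rows.append({"protein_a": a, "protein_b": b,
                     "experimental_score": score, "combined_score": combined})
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b",
                                        "experimental_score", "combined_score"])
    manifest = {
        "e2s": e2s, "e3s": e3s, "seed": seed,
        "true_edges": true_edges, "low_edges": low_edges, "nonexp_edges": nonexp_edges,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        edges.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
        (out_dir / f"{stem}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return edges, manifest


# ---------------------------------------------------------------------------
# Energetics tables
# ---------------------------------------------------------------------------

def make_energetics_table(complex_ids: Sequence[str], seed: int = 0,
                          pair_ids: Sequence[str] = (),
                          unsat_shift: float = 2.0,
                          out_path: Optional[Path] = None) -> list[EnergeticsRecord]:
    """Three interface rows per complex; planted pairs get fewer unsatisfied
    interface hydrogen bonds and more favorable binding energies."""
    rng = np.random.default_rng(seed)
    pair_ids = set(pair_ids)
    records = []
    for cid in complex_ids:
        is_pair = cid in pair_ids
        for iface in ("UB-E2", "UB-E3", "E2-E3"):
            total = float(rng.uniform(900, 1600))
            polar = float(rng.uniform(0.3, 0.6)) * total
            dg = float(rng.normal(-22.0 if is_pair else -15.0, 3.0))
            unsat = max(0, int(round(rng.normal(3.0 if is_pair else 3.0 + unsat_shift, 1.0))))
            records.append(EnergeticsRecord(
                complex_id=cid, interface=iface, dG=dg,
                dSASA_total=total, dSASA_polar=polar, dSASA_nonpolar=total - polar,
                hbonds_total=int(rng.integers(4, 12)), hbonds_unsat=unsat,
                n_interface_residues=int(rng.integers(10, 30)),
            ))
    if out_path is not None:
        from .energetics_ingest import write_energetics

        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        write_energetics(records, out_path)
    return records


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTableSpec:
    n_pairs: int = 250
    n_nonpairs: int = 250
    effect_size: float = 1.0        # standardized mean shift between classes
    noise_sd: float = 1.0
    linchpin_rate_pair: float = 0.612
    linchpin_rate_nonpair: float = 0.399
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.linchpin_rate_pair <= 1 and 0 <= self.linchpin_rate_nonpair <= 1):
            raise ValueError("linchpin rates must be in [0, 1]")
        if self.n_pairs < 1 or self.n_nonpairs < 1:
            raise ValueError("class sizes must be >= 1")


# per-feature (baseline mean, baseline sd, pair-direction sign)
_FEATURE_MODEL = {
    "ipsae": (0.45, 0.12, +1),
    "iptm": (0.55, 0.12, +1),
    "pdockq": (0.35, 0.10, +1),
    "pdockq2": (0.40, 0.12, +1),
    "dG": (-15.0, 4.0, -1),
    "dSASA": (1200.0, 200.0, +1),
    "dSASA_polar": (550.0, 120.0, +1),
    "dSASA_nonpolar": (650.0, 140.0, +1),
    "hbonds_int": (7.0, 2.0, +1),
    "hbonds_unsat": (5.0, 1.5, -1),
    "nres": (20.0, 5.0, +1),
    "ile44_helix_dist": (7.08, 0.8, -1),
    "tail_cys_dist": (4.60, 0.6, -1),
    "n_e3_loops": (2.0, 0.8, +1),
    "n_e3_loop_residues": (8.0, 2.5, +1),
}


def make_feature_table(spec: FeatureTableSpec,
                       out_dir: Optional[Path] = None,
                       stem: str = "features") -> tuple[pd.DataFrame, dict]:
    """Labeled feature table with planted class effects.

    Pair rows shift each feature mean by ``effect_size`` baseline standard
    deviations in the direction observed for functional pairs (higher
    confidence scores, lower distances, fewer unsatisfied hydrogen bonds,
    higher linchpin rate); noise is Gaussian with ``noise_sd`` times the
    baseline sd.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, count, linch_rate in (
        ("pair", spec.n_pairs, spec.linchpin_rate_pair),
        ("nonpair", spec.n_nonpairs, spec.linchpin_rate_nonpair),
    ):
        shift_sign = 1.0 if label == "pair" else 0.0
        for i in range(count):
            row = {
                "complex_id": f"{label}_{i:04d}",
                "e2": f"E2_{rng.integers(1, 32):03d}",
                "e3": f"E3_{rng.integers(1, 147):03d}",
                "label": label,
                "conformation": "Closed",
            }
            for prefix in INTERFACE_PREFIXES.values():
                for feat, (mean, sd, direction) in _FEATURE_MODEL.items():
                    if feat in COMPLEX_FEATURES:
                        continue
                    value = mean + shift_sign * spec.effect_size * direction * sd \
                        + rng.normal(0.0, spec.noise_sd * sd)
                    if feat in ("ipsae", "iptm", "pdockq", "pdockq2"):
                        value = float(np.clip(value, 0.0, 1.0))
                    row[f"{prefix}_{feat}"] = value
            for feat in ("ile44_helix_dist", "tail_cys_dist", "n_e3_loops",
                         "n_e3_loop_residues"):
                mean, sd, direction = _FEATURE_MODEL[feat]
                value = mean + shift_sign * spec.effect_size * direction * sd \
                    + rng.normal(0.0, spec.noise_sd * sd)
                row[feat] = max(0.0, value)
            row["linchpin_flag"] = int(rng.random() < linch_rate)
            rows.append(row)
    table = pd.DataFrame(rows)
    assert set(FEATURE_COLUMNS) <= set(table.columns)
    manifest = {
        "n_pairs": spec.n_pairs,
        "n_nonpairs": spec.n_nonpairs,
        "effect_size": spec.effect_size,
        "noise_sd": spec.noise_sd,
        "linchpin_rate_pair": spec.linchpin_rate_pair,
        "linchpin_rate_nonpair": spec.linchpin_rate_nonpair,
        "seed": spec.seed,
        "n_feature_columns": len(FEATURE_COLUMNS),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
        (out_dir / f"{stem}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return table, manifest
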