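"""Closed/Open conformation classification of ubiquitin-E2(-E3) complexes.

Two diagnostic distances drive the call:

* the minimum distance between the ubiquitin Ile44 Calpha and the Calpha
  atoms of the E2 crossover helix, and
* the distance between the carbonyl carbon of the ubiquitin C-terminal
  residue (canonical position 76) and the Calpha of the E2 catalytic
  cysteine.

A complex is Closed when the copy-averaged Ile44-helix distance is strictly
below the 10 A cutoff and - for predicted structures, which lack the anchoring
thioester bond - the averaged tail-cysteine distance is strictly below 12 A.
Distances exactly at a cutoff therefore yield Open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure_model import Chain, Copy, E2Entry, ReferenceSequences, Role, TernaryComplex

__all__ = [
    "CrossoverHelix",
    "CutoffParams",
    "ConformationCall",
    "ConformationError",
    "HelixDetectionError",
    "MissingResidueError",
    "secondary_structure",
    "find_crossover_helix",
    "find_catalytic_cysteine",
    "ile44_helix_distance",
    "tail_cys_distance",
    "classify_conformation",
]

# Calpha-geometry windows for helix detection (i->i+3 and i->i+4 distances)
HELIX_I3_RANGE = (4.5, 6.0)
HELIX_I4_RANGE = (5.8, 7.1)
STRAND_I2_MIN = 6.4
MIN_HELIX_LEN = 6

UB_TAIL_START = 71
UB_CTERM = 76


class ConformationError(ValueError):
    pass


class HelixDetectionError(ConformationError):
    pass


class MissingResidueError(ConformationError):
    pass


@dataclass(frozen=True)
class CrossoverHelix:
    chain_id: str
    start: int
    end: int
    source: str  # "curated" | "detected"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("helix start must not exceed end")
        if self.end - self.start + 1 < MIN_HELIX_LEN:
            raise ValueError(f"helix span must cover >= {MIN_HELIX_LEN} residues")


@dataclass(frozen=True)
class CutoffParams:
    d_ile44: float = 10.0
    d_tail: float = 12.0
    apply_tail_criterion: bool = True

    def __post_init__(self):
        if self.d_ile44 <= 0 or self.d_tail <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def experimental(cls) -> "CutoffParams":
        # the thioester bond anchors the tail, so only the Ile44 criterion applies
        return cls(apply_tail_criterion=False)

    @classmethod
    def predicted(cls) -> "CutoffParams":
        return cls(apply_tail_criterion=True)


@dataclass(frozen=True)
class ConformationCall:
    ile44_helix_dist: float
    tail_cys_dist: Optional[float]
    label: str  # "Closed" | "Open"
    cutoffs: tuple[float, float]
    n_copies_averaged: int
    tail_fallback_used: bool = False


def secondary_structure(chain: Chain) -> dict[tuple[int, str], str]:
    """Per-residue H/E/C labels from Calpha geometry only.

    A window starting at i is helical when d(i, i+3) lies in ``HELIX_I3_RANGE``
    and d(i, i+4) in ``HELIX_I4_RANGE``; the five covered residues are marked
    H. A residue j is marked E (strand, extended) when d(j-1, j+1) >=
    ``STRAND_I2_MIN`` and it is not already helical. Everything else is coil.
    """
    residues, coords = chain.ca_array()
    n = len(residues)
    labels = ["C"] * n
    for i in range(n - 4):
        d3 = np.linalg.norm(coords[i] - coords[i + 3])
        d4 = np.linalg.norm(coords[i] - coords[i + 4])
        if HELIX_I3_RANGE[0] <= d3 <= HELIX_I3_RANGE[1] and \
                HELIX_I4_RANGE[0] <= d4 <= HELIX_I4_RANGE[1]:
            for j in range(i, i + 5):
                labels[j] = "H"
    for j in range(1, n - 1):
        if labels[j] == "C" and \
                np.linalg.norm(coords[j - 1] - coords[j + 1]) >= STRAND_I2_MIN:
            labels[j] = "E"
    return {res.key: label for res, label in zip(residues, labels)}


def find_crossover_helix(e2_chain: Chain,
                         registry_entry: Optional[E2Entry] = None,
                         catalytic_cys: Optional[int] = None) -> CrossoverHelix:
    """Locate the E2 crossover helix.

    A curated registry span always wins. Otherwise the first detected
    alpha-helix of length >= 6 starting after the catalytic cysteine is
    returned.
    """
    if registry_entry is not None and registry_entry.helix_span is not None:
        start, end = registry_entry.helix_span
        return CrossoverHelix(e2_chain.chain_id, start, end, "curated")
    residues, _ = e2_chain.ca_array()
    if len(residues) < 20:
        raise HelixDetectionError(
            f"chain {e2_chain.chain_id} has fewer than 20 residues with CA atoms"
        )
    if catalytic_cys is None and registry_entry is not None:
        catalytic_cys = registry_entry.catalytic_cys
    cys_number = catalytic_cys if catalytic_cys is not None else -(10 ** 9)
    labels = secondary_structure(e2_chain)
    run: list = []
    for res in residues:
        if labels[res.key] == "H":
            run.append(res)
        else:
            if len(run) >= MIN_HELIX_LEN and run[0].number > cys_number:
                return CrossoverHelix(e2_chain.chain_id, run[0].number, run[-1].number, "detected")
            run = []
    if len(run) >= MIN_HELIX_LEN and run[0].number > cys_number:
        return CrossoverHelix(e2_chain.chain_id, run[0].number, run[-1].number, "detected")
    raise HelixDetectionError(
        f"no alpha-helix of length >= {MIN_HELIX_LEN} found after the catalytic "
        f"cysteine in chain {e2_chain.chain_id}; supply a curated span"
    )


def find_catalytic_cysteine(e2_chain: Chain, helix: CrossoverHelix,
                            registry_entry: Optional[E2Entry] = None) -> Optional[tuple[int, bool]]:
    """Return (residue number, inferred flag) of the catalytic cysteine.

    Registry annotation wins; otherwise the first cysteine within 20 residues
    N-terminal of the helix start is used and flagged as inferred. Returns
    None for cysteine-less E2s (UBE2V-type).
    """
    if registry_entry is not None:
        if registry_entry.catalytic_cys is None:
            return None
        return registry_entry.catalytic_cys, False
    candidates = [
        r for r in e2_chain.residues
        if r.name.upper() == "CYS" and helix.start - 20 <= r.number < helix.start
    ]
    if not candidates:
        return None
    return min(c.number for c in candidates), True


def _helix_ca_coords(chain: Chain, helix: CrossoverHelix) -> np.ndarray:
    coords = [
        r.ca for r in chain.residues
        if helix.start <= r.number <= helix.end and r.ca is not None
    ]
    if not coords:
        raise MissingResidueError(
            f"no resolved CA atoms in helix {helix.start}-{helix.end} of chain {chain.chain_id}"
        )
    return np.asarray(coords)


def ile44_helix_distance(ub_chain: Chain, e2_chain: Chain, helix: CrossoverHelix) -> float:
    """Minimum Calpha-Calpha distance between ubiquitin Ile44 and the helix."""
    res44 = ub_chain.ub_residue(44)
    if res44 is None or res44.ca is None:
        raise MissingResidueError(
            f"ubiquitin residue 44 (chain {ub_chain.chain_id}) has no CA atom"
        )
    helix_cas = _helix_ca_coords(e2_chain, helix)
    return float(np.min(np.linalg.norm(helix_cas - res44.ca, axis=1)))


def tail_cys_distance(ub_chain: Chain, e2_chain: Chain,
                      cys_position: int) -> tuple[float, bool]:
    """Distance from the ubiquitin C-terminal carbonyl carbon to the Cys Calpha.

    Falls back to the C-terminal-most resolved tail residue (>= canonical 71)
    when residue 76 is unresolved; the second return value flags the fallback.
    """
    cys = e2_chain.residue_by_number(cys_position)
    if cys is None or cys.ca is None:
        raise MissingResidueError(
            f"catalytic cysteine {cys_position} of chain {e2_chain.chain_id} unresolved"
        )
    fallback = False
    carbonyl = None
    res76 = ub_chain.ub_residue(UB_CTERM)
    if res76 is not None and res76.atom_coords("C") is not None:
        carbonyl = res76.atom_coords("C")
    else:
        for pos in range(UB_CTERM - 1, UB_TAIL_START - 1, -1):
            res = ub_chain.ub_residue(pos)
            if res is not None and res.atom_coords("C") is not None:
                carbonyl = res.atom_coords("C")
                fallback = True
                break
    if carbonyl is None:
        raise MissingResidueError(
            f"no resolved carbonyl carbon in the ubiquitin tail of chain {ub_chain.chain_id}"
        )
    return float(np.linalg.norm(carbonyl - cys.ca)), fallback


def _copy_e2_entry(complex: TernaryComplex, copy: Copy,
                   refs: Optional[ReferenceSequences]) -> Optional[E2Entry]:
    if refs is None:
        return None
    chain = complex.chain(copy.e2_chain)
    gene = chain.role.gene if chain.role else None
    if gene is None:
        return None
    return refs.e2_registry.get(gene)


def classify_conformation(complex: TernaryComplex,
                          params: CutoffParams,
                          refs: Optional[ReferenceSequences] = None) -> ConformationCall:
    """Classify a complex Closed or Open.

    Distances are averaged across all ternary copies before thresholding.
    Complexes whose E2 lacks a catalytic cysteine are labeled Open whenever
    the tail criterion is in force.
    """
    if not complex.copies:
        raise ConformationError("no ternary copies enumerated; run enumerate_copies first")
    ile44_values: list[float] = []
    tail_values: list[float] = []
    cysteine_absent = False
    tail_fallback = False
    for copy in complex.copies:
        ub = complex.chain(copy.ub_chain)
        e2 = complex.chain(copy.e2_chain)
        entry = _copy_e2_entry(complex, copy, refs)
        helix = find_crossover_helix(e2, registry_entry=entry)
        ile44_values.append(ile44_helix_distance(ub, e2, helix))
        cys = find_catalytic_cysteine(e2, helix, registry_entry=entry)
        if cys is None:
            cysteine_absent = True
            continue
        dist, fb = tail_cys_distance(ub, e2, cys[0])
        tail_values.append(dist)
        tail_fallback = tail_fallback or fb
    if not ile44_values:
        raise ConformationError("no copy with a computable Ile44 distance")
    ile44_mean = float(np.mean(ile44_values))
    tail_mean = float(np.mean(tail_values)) if tail_values else None
    closed = ile44_mean < params.d_ile44
    if params.apply_tail_criterion:
        if cysteine_absent or tail_mean is None:
            closed = False
        else:
            closed = closed and tail_mean < params.d_tail
    return ConformationCall(
        ile44_helix_dist=ile44_mean,
        tail_cys_dist=tail_mean,
        label="Closed" if closed else "Open",
        cutoffs=(params.d_ile44, params.d_tail),
        n_copies_averaged=len(ile44_values),
        tail_fallback_used=tail_fallback,
    )
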