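"""E3 domain classification, RING/U-box truncation spans, and labeled
pair / non-pair E2-E3 set construction from a physical-interaction edge table.

The edge table follows the STRING physical-links layout: one row per directed
or undirected edge with columns ``protein_a``, ``protein_b``,
``experimental_score`` and ``combined_score`` (scores on the 0-1000 scale).
Pairs require an experimental score of at least 400; non-pairs must have no
edge at any evidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "E3Record",
    "PairLabel",
    "ExclusionPolicy",
    "DatasetError",
    "classify_e3",
    "build_truncation",
    "candidate_pool",
    "build_pair_set",
    "build_nonpair_set",
    "apply_exclusions",
]

MIN_PAIR_SCORE = 400

DEFAULT_EXCLUDED_E2S = frozenset(
    {"UBE2L3", "UBE2L6", "UBE2L5", "UBE2V1", "UBE2V2", "UBE2I"}
)

_DOMAIN_KINDS = {"RING", "UBOX", "HECT", "IBR"}
_SOURCES = {"ECOD", "TED", "PROSITE"}


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class Domain:
    kind: str      # RING | UBOX | HECT | IBR
    source: str    # ECOD | TED | PROSITE
    start: int
    end: int

    def __post_init__(self):
        if self.kind not in _DOMAIN_KINDS:
            raise DatasetError(f"unknown domain kind {self.kind!r}")
        if self.source not in _SOURCES:
            raise DatasetError(f"unknown domain source {self.source!r}")
        if self.start > self.end:
            raise DatasetError("domain start must not exceed end")

    def overlaps(self, other: "Domain") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class E3Record:
    uniprot_id: str
    gene: str
    domains: tuple[Domain, ...] = ()
    e3_class: str = "NONE"
    truncation: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class PairLabel:
    e2: str
    e3: str
    label: str                       # "pair" | "nonpair"
    evidence_score: Optional[int] = None
    provenance: str = ""


@dataclass(frozen=True)
class ExclusionPolicy:
    excluded_e2s: frozenset = DEFAULT_EXCLUDED_E2S
    exclude_rbr: bool = True


def classify_e3(domains: Iterable[Domain | str]) -> str:
    """Map a domain set to an E3 class.

    HECT+RING -> ATYPICAL; HECT -> HECT; U-box -> UBOX; RING with IBR -> RBR;
    RING alone -> RING; nothing relevant -> NONE. When several rules could
    fire the precedence is ATYPICAL > HECT > UBOX > RBR > RING.
    """
    kinds = {d if isinstance(d, str) else d.kind for d in domains}
    has_ring = "RING" in kinds
    has_hect = "HECT" in kinds
    if has_ring and has_hect:
        return "ATYPICAL"
    if has_hect:
        return "HECT"
    if "UBOX" in kinds:
        return "UBOX"
    if has_ring and "IBR" in kinds:
        return "RBR"
    if has_ring:
        return "RING"
    return "NONE"


def build_truncation(domains: Sequence[Domain]) -> tuple[int, int]:
    """Covering span over all RING/U-box domains for structure modeling.

    ECOD RING/U-box domains are used when present, each expanded to the union
    with any overlapping TED domain; otherwise PROSITE RING/U-box spans are
    the fallback. Multiple domains merge into one covering span (interior
    sequence is intentionally retained).
    """
    ecod = [d for d in domains if d.source == "ECOD" and d.kind in ("RING", "UBOX")]
    ted = [d for d in domains if d.source == "TED"]
    if ecod:
        intervals = []
        for dom in ecod:
            start, end = dom.start, dom.end
            for t in ted:
                if dom.overlaps(t):
                    start, end = min(start, t.start), max(end, t.end)
            intervals.append((start, end))
        return (min(s for s, _ in intervals), max(e for _, e in intervals))
    prosite = [d for d in domains if d.source == "PROSITE" and d.kind in ("RING", "UBOX")]
    if prosite:
        return (min(d.start for d in prosite), max(d.end for d in prosite))
    raise DatasetError("no RING/U-box domain from any source; cannot build truncation")


def _normalize_edges(edges: pd.DataFrame) -> pd.DataFrame:
    required = {"protein_a", "protein_b"}
    if not required <= set(edges.columns):
        raise DatasetError(f"edge table must have columns {sorted(required)}")
    out = edges.copy()
    if "experimental_score" not in out.columns:
        out["experimental_score"] = 0
    if "combined_score" not in out.columns:
        out["combined_score"] = out["experimental_score"]
    return out


def candidate_pool(e2s: Iterable[str], e3s: Iterable[str]) -> list[tuple[str, str]]:
    """All E2 x E3 combinations, sorted deterministically."""
    return [(e2, e3) for e2 in sorted(set(e2s)) for e3 in sorted(set(e3s))]


def build_pair_set(edges: pd.DataFrame, e2_list: Iterable[str], e3_list: Iterable[str],
                   min_score: int = MIN_PAIR_SCORE) -> list[PairLabel]:
    """E2-E3 edges with experimental evidence >= ``min_score`` (inclusive),
    deduplicated across edge direction."""
    edges = _normalize_edges(edges)
    e2_set, e3_set = set(e2_list), set(e3_list)
    best: dict[tuple[str, str], int] = {}
    for row in edges.itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        score = int(row.experimental_score)
        for e2, e3 in ((a, b), (b, a)):
            if e2 in e2_set and e3 in e3_set:
                key = (e2, e3)
                if score > best.get(key, -1):
                    best[key] = score
    return [
        PairLabel(e2, e3, "pair", evidence_score=score,
                  provenance=f"experimental_score>={min_score}")
        for (e2, e3), score in sorted(best.items())
        if score >= min_score
    ]


def _any_evidence(edges: pd.DataFrame, e2_set: set, e3_set: set) -> set[tuple[str, str]]:
    hits = set()
    for row in edges.itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        if int(row.combined_score) <= 0 and int(row.experimental_score) <= 0:
            continue
        for e2, e3 in ((a, b), (b, a)):
            if e2 in e2_set and e3 in e3_set:
                hits.add((e2, e3))
    return hits


def build_nonpair_set(pair_set: Sequence[PairLabel], edges: pd.DataFrame,
                      n: int, seed: int) -> list[PairLabel]:
    """Uniform deterministic sample of n non-pairs.

    Candidates are the Cartesian product of the pair set's unique E2s and E3s,
    minus combinations with any edge at any evidence level and minus the pair
    set itself.
    """
    if not pair_set:
        raise DatasetError("pair set is empty")
    edges = _normalize_edges(edges)
    e2s = {p.e2 for p in pair_set}
    e3s = {p.e3 for p in pair_set}
    pool = candidate_pool(e2s, e3s)
    evidence = _any_evidence(edges, e2s, e3s)
    pairs = {(p.e2, p.e3) for p in pair_set}
    candidates = [c for c in pool if c not in evidence and c not in pairs]
    if len(candidates) < n:
        raise DatasetError(
            f"candidate pool has only {len(candidates)} combinations; {n} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [
        PairLabel(candidates[i][0], candidates[i][1], "nonpair",
                  provenance=f"no-evidence sample seed={seed}")
        for i in sorted(chosen)
    ]


def apply_exclusions(dataset: Sequence[PairLabel], policy: ExclusionPolicy,
                     e3_records: dict[str, E3Record]) -> tuple[list[PairLabel], dict]:
    """Drop rows with excluded E2s and (optionally) RBR-class E3s.

    Returns the filtered dataset and removal counts by reason.
    """
    kept: list[PairLabel] = []
    removed = {"excluded_e2": 0, "rbr_e3": 0}
    for row in dataset:
        if row.e2 in policy.excluded_e2s:
            removed["excluded_e2"] += 1
            continue
        if policy.exclude_rbr:
            record = e3_records.get(row.e3)
            if record is None:
                raise DatasetError(f"no class record for E3 {row.e3}")
            if record.e3_class == "RBR":
                removed["rbr_e3"] += 1
                continue
        kept.append(row)
    return kept, removed


def load_domain_table(path) -> dict[str, E3Record]:
    """Read a domain annotation TSV (uniprot_id, gene, kind, source, start,
    end) into classified E3 records with truncation spans where possible."""
    df = pd.read_csv(path, sep="\t")
    records: dict[str, E3Record] = {}
    grouped: dict[str, list[Domain]] = {}
    genes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(row.uniprot_id, []).append(
            Domain(str(row.kind), str(row.source), int(row.start), int(row.end))
        )
        genes[row.uniprot_id] = str(getattr(row, "gene", row.uniprot_id))
    for uniprot_id, domains in grouped.items():
        e3_class = classify_e3(domains)
        try:
            trunc = build_truncation(domains)
        except DatasetError:
            trunc = None
        records[genes[uniprot_id]] = E3Record(
            uniprot_id, genes[uniprot_id], tuple(domains), e3_class, trunc
        )
    return records
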