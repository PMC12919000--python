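"""Ingest per-interface energetics tables from an external interface-analysis
tool.

The tool itself is never invoked; this module only defines the TSV contract
(header: complex_id, interface, dG, dSASA, dSASA_polar, dSASA_nonpolar,
hbonds_int, hbonds_unsat, nres) and normalizes rows into feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "EnergeticsRecord",
    "EnergeticsError",
    "ENERGETICS_COLUMNS",
    "parse_energetics",
    "records_to_frame",
    "write_energetics",
    "merge_energetics",
]

ENERGETICS_COLUMNS = [
    "complex_id", "interface", "dG", "dSASA", "dSASA_polar",
    "dSASA_nonpolar", "hbonds_int", "hbonds_unsat", "nres",
]

EXPECTED_INTERFACES = ("UB-E2", "UB-E3", "E2-E3")

_SASA_TOL = 1e-3


class EnergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class EnergeticsRecord:
    complex_id: str
    interface: str
    dG: float
    dSASA_total: float
    dSASA_polar: float
    dSASA_nonpolar: float
    hbonds_total: int
    hbonds_unsat: int
    n_interface_residues: int

    def __post_init__(self):
        if self.dSASA_polar > self.dSASA_total + _SASA_TOL or \
                self.dSASA_nonpolar > self.dSASA_total + _SASA_TOL:
            raise EnergeticsError(
                f"{self.complex_id}/{self.interface}: SASA component exceeds total"
            )
        if min(self.hbonds_total, self.hbonds_unsat, self.n_interface_residues) < 0:
            raise EnergeticsError(f"{self.complex_id}/{self.interface}: negative count")


def parse_energetics(path, dialect: str = "default") -> tuple[list[EnergeticsRecord], list[str]]:
    """Parse an energetics TSV.

    Returns the records plus a list of flags for complexes missing one or more
    of the three expected interfaces. Duplicate (complex, interface) rows are
    an error.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(ENERGETICS_COLUMNS) - set(df.columns)
    if missing_cols:
        raise EnergeticsError(f"{path}: missing columns {sorted(missing_cols)}")
    seen = set()
    records = []
    for row in df.itertuples(index=False):
        key = (row.complex_id, row.interface)
        if key in seen:
            raise EnergeticsError(f"{path}: duplicate row for {key}")
        seen.add(key)
        records.append(EnergeticsRecord(
            complex_id=str(row.complex_id),
            interface=str(row.interface),
            dG=float(row.dG),
            dSASA_total=float(row.dSASA),
            dSASA_polar=float(row.dSASA_polar),
            dSASA_nonpolar=float(row.dSASA_nonpolar),
            hbonds_total=int(row.hbonds_int),
            hbonds_unsat=int(row.hbonds_unsat),
            n_interface_residues=int(row.nres),
        ))
    flags = []
    by_complex: dict[str, set[str]] = {}
    for rec in records:
        by_complex.setdefault(rec.complex_id, set()).add(rec.interface)
    for cid, interfaces in sorted(by_complex.items()):
        absent = [i for i in EXPECTED_INTERFACES if i not in interfaces]
        if absent:
            flags.append(f"{cid}: missing interfaces {absent}")
    return records, flags


def records_to_frame(records: Sequence[EnergeticsRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "complex_id": r.complex_id,
            "interface": r.interface,
            "dG": r.dG,
            "dSASA": r.dSASA_total,
            "dSASA_polar": r.dSASA_polar,
            "dSASA_nonpolar": r.dSASA_nonpolar,
            "hbonds_int": r.hbonds_total,
            "hbonds_unsat": r.hbonds_unsat,
            "nres": r.n_interface_residues,
        }
        for r in records
    ], columns=ENERGETICS_COLUMNS)


def write_energetics(records: Sequence[EnergeticsRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def merge_energetics(features: pd.DataFrame,
                     records: Sequence[EnergeticsRecord]) -> tuple[pd.DataFrame, list[str]]:
    """Left-join energetics onto a per-(complex, interface) feature table.

    Feature rows are never duplicated or dropped; unmatched energetics rows
    are reported. Merging twice is a no-op (energetics columns are replaced).
    """
    if not {"complex_id", "interface"} <= set(features.columns):
        raise EnergeticsError("feature table needs complex_id and interface columns")
    energy = records_to_frame(records)
    value_cols = [c for c in ENERGETICS_COLUMNS if c not in ("complex_id", "interface")]
    base = features.drop(columns=[c for c in value_cols if c in features.columns])
    merged = base.merge(energy, on=["complex_id", "interface"], how="left")
    assert len(merged) == len(features)
    feature_keys = set(zip(features["complex_id"], features["interface"]))
    unmatched = [
        f"{r.complex_id}/{r.interface}" for r in records
        if (r.complex_id, r.interface) not in feature_keys
    ]
    return merged, unmatched
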