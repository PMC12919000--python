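"""Interface confidence metrics from prediction-confidence files.

Consumes per-residue pLDDT, the residue x residue PAE matrix and (when
present) chain-pair ipTM values, in either of two JSON dialects:

* ``af3``: ``{"pae": [[...]], "token_chain_ids": [...], "token_res_ids":
  [...], "plddt": [...], "chain_ids": [...], "chain_pair_iptm": [[...]]}``
* ``colabfold``: ``{"pae": [[...]], "plddt": [...]}`` - chain spans must be
  supplied by the caller (from the structure file or a generator manifest).

Computes the mean interface PAE, ipSAE, pDockQ2, pDockQ and a PAE-derived
pairwise ipTM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import constants
from .constants import PAE_THRESHOLD, tm_d0

__all__ = [
    "PredictionConfidence",
    "ScoreParams",
    "ConfidenceRecord",
    "ConfidenceError",
    "load_confidence",
    "mean_interface_pae",
    "ipsae",
    "pdockq2",
    "pdockq",
    "interface_iptm",
]


class ConfidenceError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreParams:
    pae_threshold: float = PAE_THRESHOLD
    d0_floor: float = constants.D0_FLOOR
    interface_cutoff: float = 8.0

    def __post_init__(self):
        if self.pae_threshold <= 0:
            raise ValueError("PAE threshold must be positive")


@dataclass
class PredictionConfidence:
    plddt: np.ndarray                       # (n,) in [0, 100]
    pae: np.ndarray                         # (n, n) in A
    chain_spans: dict                       # chain_id -> (start, stop) half-open
    chain_pair_iptm: dict = field(default_factory=dict)  # (ci, cj) -> [0, 1]

    def __post_init__(self):
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.pae.shape[0]
        if self.pae.ndim != 2 or self.pae.shape != (n, n):
            raise ConfidenceError("PAE matrix must be square")
        if self.plddt.shape != (n,):
            raise ConfidenceError("pLDDT length must equal PAE dimension")
        if np.any(self.pae < 0):
            raise ConfidenceError("PAE entries must be non-negative")
        total = sum(stop - start for start, stop in self.chain_spans.values())
        if total != n:
            raise ConfidenceError(
                f"chain spans cover {total} residues but PAE dimension is {n}"
            )

    def span(self, chain_id: str) -> range:
        start, stop = self.chain_spans[chain_id]
        return range(start, stop)

    def n_residues(self, chain_id: str) -> int:
        start, stop = self.chain_spans[chain_id]
        return stop - start


def _spans_from_lengths(chain_ids: Sequence[str], lengths: Sequence[int]) -> dict:
    spans, offset = {}, 0
    for cid, length in zip(chain_ids, lengths):
        spans[cid] = (offset, offset + length)
        offset += length
    return spans


def load_confidence(path, dialect: str,
                    chain_spans: Optional[Mapping[str, tuple[int, int]]] = None,
                    n_residues: Optional[int] = None) -> PredictionConfidence:
    """Parse a confidence JSON file.

    ``chain_spans`` is required for the colabfold dialect (no chain metadata in
    the file). ``n_residues`` (when known from the structure) is checked
    against the matrix dimension.
    """
    with open(path) as fh:
        data = json.load(fh)
    pae = np.asarray(data["pae"], dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ConfidenceError(f"{path}: PAE matrix is not square")
    if n_residues is not None and pae.shape[0] != n_residues:
        raise ConfidenceError(
            f"{path}: PAE dimension {pae.shape[0]} does not match structure "
            f"residue count {n_residues}"
        )
    if dialect == "af3":
        token_chains = data["token_chain_ids"]
        if len(token_chains) != pae.shape[0]:
            raise ConfidenceError(f"{path}: token_chain_ids length mismatch")
        spans: dict = {}
        for idx, cid in enumerate(token_chains):
            if cid not in spans:
                spans[cid] = (idx, idx + 1)
            else:
                start, stop = spans[cid]
                if idx != stop:
                    raise ConfidenceError(f"{path}: chain {cid} tokens are not contiguous")
                spans[cid] = (start, idx + 1)
        plddt = np.asarray(data["plddt"], dtype=float)
        pair_iptm = {}
        if "chain_pair_iptm" in data:
            chain_ids = data.get("chain_ids", sorted(spans))
            matrix = data["chain_pair_iptm"]
            for i, ci in enumerate(chain_ids):
                for j, cj in enumerate(chain_ids):
                    if i != j:
                        pair_iptm[(ci, cj)] = float(matrix[i][j])
        return PredictionConfidence(plddt, pae, spans, pair_iptm)
    if dialect == "colabfold":
        if chain_spans is None:
            raise ConfidenceError("colabfold dialect requires explicit chain_spans")
        plddt = np.asarray(data["plddt"], dtype=float)
        return PredictionConfidence(plddt, pae, dict(chain_spans))
    raise ConfidenceError(f"unknown dialect {dialect!r}")


def _indices(conf: PredictionConfidence, chain_id: str,
             local: Optional[Sequence[int]] = None) -> np.ndarray:
    start, stop = conf.chain_spans[chain_id]
    if local is None:
        return np.arange(start, stop)
    return start + np.asarray(sorted(local), dtype=int)


def mean_interface_pae(conf: PredictionConfidence, chain_a: str, chain_b: str,
                       iface_a: Sequence[int], iface_b: Sequence[int]) -> Optional[float]:
    """Mean of pae[i, j] and pae[j, i] over all inter-chain residue pairs with
    both residues in the interface. ``iface_*`` are chain-local residue
    indices. Returns None for an empty interface."""
    if len(iface_a) == 0 or len(iface_b) == 0:
        return None
    ia = _indices(conf, chain_a, iface_a)
    ib = _indices(conf, chain_b, iface_b)
    block_ab = conf.pae[np.ix_(ia, ib)]
    block_ba = conf.pae[np.ix_(ib, ia)]
    return float((block_ab.mean() + block_ba.mean()) / 2.0)


@dataclass(frozen=True)
class DirectionalScore:
    ab: float
    ba: float

    @property
    def aggregate(self) -> float:
        return max(self.ab, self.ba)


def ipsae(conf: PredictionConfidence, chain_pair: tuple[str, str],
          params: ScoreParams = ScoreParams()) -> DirectionalScore:
    """ipSAE for a chain pair.

    Per alignment direction, inter-chain pairs with PAE strictly below the
    threshold are averaged through 1/(1 + (PAE/d0)^2), with d0 computed from
    the number of distinct scored-chain residues in qualifying pairs. The
    aggregate is the maximum over the two directions; a direction with no
    qualifying pair scores 0.
    """
    ca, cb = chain_pair

    def one_direction(aligned: str, scored: str) -> float:
        rows = _indices(conf, aligned)
        cols = _indices(conf, scored)
        block = conf.pae[np.ix_(rows, cols)]
        mask = block < params.pae_threshold
        if not mask.any():
            return 0.0
        n_scored = int(np.count_nonzero(mask.any(axis=0)))
        d0 = tm_d0(n_scored, params.d0_floor)
        vals = 1.0 / (1.0 + (block[mask] / d0) ** 2)
        return float(vals.mean())

    return DirectionalScore(one_direction(ca, cb), one_direction(cb, ca))


def pdockq2(conf: PredictionConfidence, chain_a: str, chain_b: str,
            iface_a: Sequence[int], iface_b: Sequence[int]) -> Optional[float]:
    """pDockQ2 over a chain-pair interface.

    x = mean interface pLDDT * mean over interface residue pairs (both
    orientations) of 1/(1 + (PAE/10)^2), pushed through the published sigmoid.
    Returns None for an empty interface.
    """
    if len(iface_a) == 0 or len(iface_b) == 0:
        return None
    ia = _indices(conf, chain_a, iface_a)
    ib = _indices(conf, chain_b, iface_b)
    plddt_mean = float(conf.plddt[np.concatenate([ia, ib])].mean())
    block = np.concatenate([conf.pae[np.ix_(ia, ib)].ravel(),
                            conf.pae[np.ix_(ib, ia)].ravel()])
    term = float(np.mean(1.0 / (1.0 + (block / constants.PDOCKQ2_D0) ** 2)))
    x = plddt_mean * term
    return constants.sigmoid(x, constants.PDOCKQ2_L, constants.PDOCKQ2_X0,
                             constants.PDOCKQ2_K, constants.PDOCKQ2_B)


def pdockq(conf: PredictionConfidence, chain_a: str, chain_b: str,
           iface_a: Sequence[int], iface_b: Sequence[int],
           n_contacts: int) -> Optional[float]:
    """Original pDockQ: sigmoid of mean interface pLDDT * log(contacts)."""
    if n_contacts <= 0 or len(iface_a) == 0 or len(iface_b) == 0:
        return None
    ia = _indices(conf, chain_a, iface_a)
    ib = _indices(conf, chain_b, iface_b)
    plddt_mean = float(conf.plddt[np.concatenate([ia, ib])].mean())
    x = plddt_mean * math.log(n_contacts)
    return constants.sigmoid(x, constants.PDOCKQ_L, constants.PDOCKQ_X0,
                             constants.PDOCKQ_K, constants.PDOCKQ_B)


def interface_iptm(conf: PredictionConfidence, chain_pair: tuple[str, str],
                   d0_floor: float = constants.D0_FLOOR) -> float:
    """Chain-pair ipTM: the stored value when present, otherwise a pairwise
    pTM-style score computed from the PAE matrix.

    The computed form uses d0 of the combined chain length; for each aligned
    residue the transform is averaged over the partner chain, and the score is
    the maximum over aligned residues, aggregated over both directions by max.
    """
    ca, cb = chain_pair
    stored = conf.chain_pair_iptm.get((ca, cb))
    if stored is None:
        stored = conf.chain_pair_iptm.get((cb, ca))
    if stored is not None:
        return float(stored)
    if ca not in conf.chain_spans or cb not in conf.chain_spans:
        raise ConfidenceError(f"no ipTM source for chain pair {chain_pair}")
    n_total = conf.n_residues(ca) + conf.n_residues(cb)
    d0 = tm_d0(n_total, d0_floor)

    def one_direction(aligned: str, scored: str) -> float:
        rows = _indices(conf, aligned)
        cols = _indices(conf, scored)
        block = conf.pae[np.ix_(rows, cols)]
        per_residue = np.mean(1.0 / (1.0 + (block / d0) ** 2), axis=1)
        return float(per_residue.max())

    return max(one_direction(ca, cb), one_direction(cb, ca))


@dataclass(frozen=True)
class ConfidenceRecord:
    interface: str
    mean_interface_pae: Optional[float]
    ipsae: float
    pdockq2: Optional[float]
    pdockq: Optional[float]
    iptm: float
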