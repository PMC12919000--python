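"""Numeric constants for PAE-derived interface scores.

The d0 size law is the TM-score form d0(n) = 1.24 * (n - 15)^(1/3) - 1.8,
clamped below. pDockQ2 sigmoid: L / (1 + exp(-k (x - x0))) + b with
L = 1.31, x0 = 84.733, k = 0.075, b = 0.005 and a fixed d0 of 10 A inside its
PAE transform. pDockQ (version 1) sigmoid: 0.724 / (1 + exp(-0.052 (x -
152.611))) + 0.018 with x = mean interface pLDDT * log(number of interface
contacts).
"""

from __future__ import annotations

import math

# TM-score style size law
D0_COEFF = 1.24
D0_OFFSET = 15.0
D0_SHIFT = 1.8
D0_FLOOR = 1.0

# ipSAE / interface-PAE
PAE_THRESHOLD = 10.0

# pDockQ2 (fixed constants of the published sigmoid)
PDOCKQ2_L = 1.31
PDOCKQ2_X0 = 84.733
PDOCKQ2_K = 0.075
PDOCKQ2_B = 0.005
PDOCKQ2_D0 = 10.0

# pDockQ version 1
PDOCKQ_L = 0.724
PDOCKQ_X0 = 152.611
PDOCKQ_K = 0.052
PDOCKQ_B = 0.018
PDOCKQ_CONTACT_CUTOFF = 8.0


def tm_d0(n_residues: float, floor: float = D0_FLOOR) -> float:
    """TM-score d0 for a system of ``n_residues``, clamped below by ``floor``."""
    if n_residues <= D0_OFFSET:
        return floor
    return max(floor, D0_COEFF * (n_residues - D0_OFFSET) ** (1.0 / 3.0) - D0_SHIFT)


def sigmoid(x: float, L: float, x0: float, k: float, b: float) -> float:
    return L / (1.0 + math.exp(-k * (x - x0))) + b
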