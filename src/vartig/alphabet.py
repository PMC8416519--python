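"""Amino-acid alphabet, BLOSUM62 scoring and background composition.

All column-frequency vectors and PSSMs in this package are indexed by the
canonical 20-letter alphabet in :data:`AA` order. Gap characters are ``-``
(and ``.`` on input); ``X`` is accepted in sequences but carries no count.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP = "-"

#: Background amino-acid frequencies used for PSSM log-odds and for the
#: "random mixture" anchor of the homogeneity score (BLOSUM62 marginals).
BACKGROUND = np.array(
    [
        0.074,  # A
        0.025,  # C
        0.054,  # D
        0.054,  # E
        0.047,  # F
        0.074,  # G
        0.026,  # H
        0.068,  # I
        0.058,  # K
        0.099,  # L
        0.025,  # M
        0.045,  # N
        0.039,  # P
        0.034,  # Q
        0.052,  # R
        0.057,  # S
        0.051,  # T
        0.073,  # V
        0.013,  # W
        0.032,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def _load_blosum62() -> np.ndarray:
    full = substitution_matrices.load("BLOSUM62")
    m = np.empty((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            m[i, j] = full[a, b]
    return m


#: BLOSUM62 restricted to the 20 canonical residues, AA order.
BLOSUM62 = _load_blosum62()

# Expected pair score between two background-drawn residues; the zero anchor
# of the homogeneity scale.
RANDOM_PAIR_SCORE = float(BACKGROUND @ BLOSUM62 @ BACKGROUND)


def _conditional_replacement() -> np.ndarray:
    """P(b | a, b != a) from BLOSUM62 implied target frequencies.

    q_ab ~ p_a p_b 2^(S_ab/2); rows renormalised with the diagonal removed.
    Used by the sequence simulator to draw replacement residues.
    """
    q = np.outer(BACKGROUND, BACKGROUND) * np.exp2(BLOSUM62 / 2.0)
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)


REPLACEMENT_PROBS = _conditional_replacement()


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 index array; gaps -> -1, X/unknown -> -2."""
    out = np.full(len(seq), -2, dtype=np.int8)
    for i, c in enumerate(seq):
        if c in AA_INDEX:
            out[i] = AA_INDEX[c]
        elif c in "-.":
            out[i] = -1
    return out


def decode(idx: np.ndarray) -> str:
    return "".join(AA[i] if i >= 0 else GAP for i in idx)
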