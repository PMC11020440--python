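"""Amino-acid alphabet shared by all modules.

The state space has 21 symbols: the 20 standard amino acids plus the
alignment gap.  The gap participates in frequency counting and in the
Potts model as an ordinary state; conservation scores exclude it.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, in a fixed canonical order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Gap symbol; index 20 in the encoded alphabet.
GAP: str = "-"

#: Full 21-state alphabet (20 amino acids + gap).
ALPHABET: str = AMINO_ACIDS + GAP

#: Number of states including the gap.
N_STATES: int = 21

#: Index of the gap state.
GAP_INDEX: int = 20

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
_CODE["."] = GAP_INDEX  # alternative gap symbol used by some aligners

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def is_standard_aa(char: str) -> bool:
    """True if ``char`` is one of the 20 standard one-letter codes."""
    return char in _CODE and char != "." and char != GAP


def encode_char(char: str) -> int:
    """Map one character to its state index.

    Nonstandard residue codes (B, Z, X, U, O, J, ...) canonicalize to the
    gap state rather than being dropped, so alignment depth and column
    register are preserved.
    """
    return _CODE.get(char.upper(), GAP_INDEX)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence string into an int8 array of state indices."""
    return np.fromiter((encode_char(c) for c in seq), dtype=np.int8, count=len(seq))


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return "".join(ALPHABET[int(c)] for c in codes)
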