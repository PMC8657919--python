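"""Residue alphabet shared across the toolkit.

The alphabet has 21 symbols: the 20 standard amino acids plus a single
shared symbol ``X`` for unknown residues, gaps, and padding.  Non-standard
one-letter codes (B, Z, U, O, J) and the gap characters ``-``/``.`` all map
to index 20.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
GAP = "-"
ALPHABET = AMINO_ACIDS + UNKNOWN  # 21 symbols; index 20 = unknown/gap
N_STATES = len(ALPHABET)

AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNKNOWN_INDEX = 20

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common non-standard residues collapse onto the shared symbol or
    # their parent amino acid
    "MSE": "M", "SEC": "X", "PYL": "X", "ASX": "X", "GLX": "X",
}


def encode_residue(letter: str) -> int:
    """Map a one-letter residue code to its 0..20 alphabet index."""
    return AA_TO_INDEX.get(letter.upper(), UNKNOWN_INDEX)


def sanitize(letter: str) -> str:
    """Canonical one-letter code: standard amino acid, or ``X``."""
    up = letter.upper()
    return up if up in AA_TO_INDEX else UNKNOWN


def encode_sequence(seq: str) -> "list[int]":
    return [encode_residue(c) if c not in (GAP, ".") else UNKNOWN_INDEX for c in seq]
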