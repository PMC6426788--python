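"""Amino-acid alphabet, gap conventions and background distributions."""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")
GAP = "-"
AMBIGUOUS = "X"

#: Characters legal in an unaligned protein sequence.
SEQUENCE_CHARS = frozenset(AMINO_ACIDS) | {AMBIGUOUS}
#: Characters legal in an alignment row.
ALIGNMENT_CHARS = SEQUENCE_CHARS | GAP_CHARS


def uniform_background() -> np.ndarray:
    """Uniform background over the 20 amino acids."""
    return np.full(20, 1.0 / 20.0)


def validate_background(background: np.ndarray) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (20,):
        raise ValueError("background must have 20 entries")
    if np.any(bg <= 0):
        raise ValueError("background probabilities must be positive")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    return bg


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a protein sequence as indices into AMINO_ACIDS; 'X' becomes -1.

    Raises ValueError on any other character.
    """
    seq = sequence.upper()
    bad = set(seq) - SEQUENCE_CHARS
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def is_gap(char: str) -> bool:
    return char in GAP_CHARS
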