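"""Position-specific scoring profiles built from seed-alignment column slices.

A profile is built from a slice of a seed alignment (e.g. the N-terminal
columns of a peptidase family seed for the catalytic p20 subunit, the
C-terminal columns for the small p10 subunit).  Columns with residue
occupancy of at least 50% become match columns; each match column carries
log-odds emission scores in bits against a background distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from .alphabet import (
    AA_INDEX,
    ALIGNMENT_CHARS,
    AMINO_ACIDS,
    GAP_CHARS,
    uniform_background,
    validate_background,
)

#: Minimum fraction of non-gap rows for a seed column to become a match column.
MATCH_OCCUPANCY = 0.5


@dataclass(frozen=True)
class SeedAlignment:
    """A multiple alignment of seed sequences over amino acids plus gaps."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("seed alignment has no rows")
        lengths = {len(aligned) for _, aligned in self.rows}
        if len(lengths) != 1:
            raise ValueError("seed alignment rows differ in length")
        (n,) = lengths
        if n < 1:
            raise ValueError("seed alignment has zero columns")
        for name, aligned in self.rows:
            bad = set(aligned.upper()) - ALIGNMENT_CHARS
            if bad:
                raise ValueError(f"row {name!r} has illegal characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, index: int) -> str:
        """1-based column as a string of per-row characters."""
        return "".join(aligned[index - 1] for _, aligned in self.rows)

    @classmethod
    def from_file(cls, path: str | Path, fmt: str | None = None) -> "SeedAlignment":
        """Read a seed alignment from Stockholm or aligned-FASTA.

        The format is inferred from the suffix (.sto/.stk -> stockholm,
        otherwise fasta) unless given explicitly.
        """
        path = Path(path)
        if fmt is None:
            fmt = "stockholm" if path.suffix in {".sto", ".stk", ".stockholm"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        rows = tuple((rec.id, str(rec.seq).upper().replace(".", "-")) for rec in aln)
        return cls(rows)


@dataclass(frozen=True)
class ProfileModel:
    """Log-odds scoring model over the match columns of a seed slice.

    emissions[k, a] is the bit score of amino acid ``a`` at match column
    ``k``; match_columns holds the 1-based source-alignment column index of
    each match column.
    """

    name: str
    match_columns: tuple[int, ...]
    emissions: np.ndarray  # (n_match, 20) bits
    probabilities: np.ndarray  # (n_match, 20) smoothed column probabilities
    background: np.ndarray  # (20,)
    gap_open: float = 4.0
    gap_extend: float = 0.25
    source_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.match_columns) == 0:
            raise ValueError("profile has no match columns")
        mc = np.asarray(self.match_columns)
        if np.any(np.diff(mc) <= 0):
            raise ValueError("match columns must be strictly increasing")
        validate_background(self.background)
        sums = self.probabilities.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("column probability vectors must sum to 1")

    @property
    def n_columns(self) -> int:
        return len(self.match_columns)

    def consensus(self) -> str:
        """Highest-probability residue at each match column."""
        return "".join(AMINO_ACIDS[i] for i in self.probabilities.argmax(axis=1))

    def consensus_score(self) -> float:
        """Sum of emission bits along the consensus residues."""
        idx = self.probabilities.argmax(axis=1)
        return float(self.emissions[np.arange(self.n_columns), idx].sum())


def _column_counts(seed: SeedAlignment, col: int) -> tuple[np.ndarray, int]:
    """Residue counts and occupancy count for a 1-based seed column.

    'X' counts toward occupancy but contributes no residue count.
    """
    counts = np.zeros(20)
    occupied = 0
    for ch in seed.column(col).upper():
        if ch in GAP_CHARS:
            continue
        occupied += 1
        idx = AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    return counts, occupied


def build_profile(
    seed: SeedAlignment,
    first: int,
    last: int,
    background: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
    gap_open: float = 4.0,
    gap_extend: float = 0.25,
) -> ProfileModel:
    """Build a log-odds profile from columns ``first..last`` (1-based) of a seed.

    Columns with residue occupancy >= 50% become match columns.  Column
    probabilities are pseudocount-smoothed toward the background:

        p_a = (c_a + w * q_a) / (n + w)

    with ``c_a`` the residue count, ``n`` the total residue count, ``q`` the
    background and ``w`` the pseudocount weight.  Emissions are
    ``log2(p_a / q_a)`` bits.
    """
    if not (1 <= first <= last <= seed.n_columns):
        raise ValueError(
            f"column slice {first}..{last} outside seed with {seed.n_columns} columns"
        )
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = validate_background(background if background is not None else uniform_background())

    match_cols: list[int] = []
    probs: list[np.ndarray] = []
    for col in range(first, last + 1):
        counts, occupied = _column_counts(seed, col)
        if occupied / seed.n_rows < MATCH_OCCUPANCY:
            continue
        n = counts.sum()
        p = (counts + pseudocount_weight * bg) / (n + pseudocount_weight)
        match_cols.append(col)
        probs.append(p)
    if not match_cols:
        raise ValueError("no conserved columns in the requested seed slice")

    prob = np.vstack(probs)
    emissions = np.log2(prob / bg)
    return ProfileModel(
        name=name,
        match_columns=tuple(match_cols),
        emissions=emissions,
        probabilities=prob,
        background=bg,
        gap_open=gap_open,
        gap_extend=gap_extend,
        source_range=(first, last),
    )
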