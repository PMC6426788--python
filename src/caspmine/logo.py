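"""Above-background information-content sequence logos.

Per alignment column the information content is the relative entropy
(Kullback-Leibler divergence, in bits) of the smoothed residue frequencies
against a background distribution; letter heights are assigned only to
residues enriched above background (p_a > q_a), scaled by the column IC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, GAP_CHARS, validate_background

logger = logging.getLogger(__name__)


@dataclass
class LogoTable:
    """Per-column information content, letter heights and occupancy."""

    ic: np.ndarray  # (n_columns,) bits
    heights: np.ndarray  # (n_columns, 20) bits
    occupancy: np.ndarray  # (n_columns,) fraction of non-gap rows
    dyad_columns: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=list(AMINO_ACIDS))
        df.insert(0, "column", np.arange(1, len(self.ic) + 1))
        df.insert(1, "ic_bits", self.ic)
        df.insert(2, "occupancy", self.occupancy)
        return df

    def top_letter(self, column: int) -> str:
        """Highest letter at a 1-based column."""
        return AMINO_ACIDS[int(self.heights[column - 1].argmax())]


def column_probabilities(
    msa_column: str,
    pseudocount_weight: float = 0.0,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Smoothed residue probabilities and occupancy for one column.

    Gaps reduce occupancy but carry no probability mass.  An all-gap column
    has occupancy 0 and falls back to the background distribution.
    """
    from .alphabet import uniform_background

    bg = validate_background(background if background is not None else uniform_background())
    if len(msa_column) == 0:
        raise ValueError("column is empty")
    counts = np.zeros(20)
    occupied = 0
    for ch in msa_column.upper():
        if ch in GAP_CHARS:
            continue
        occupied += 1
        idx = AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    occupancy = occupied / len(msa_column)
    n = counts.sum()
    if n == 0:
        return bg.copy(), 0.0
    p = (counts + pseudocount_weight * bg) / (n + pseudocount_weight)
    return p, occupancy


def information_content(
    p: np.ndarray, background: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Relative entropy in bits and above-background letter heights.

    IC = sum_a p_a log2(p_a / q_a); height_a = p_a * IC for letters with
    p_a > q_a, zero otherwise.
    """
    from .alphabet import uniform_background

    q = validate_background(background if background is not None else uniform_background())
    p = np.asarray(p, dtype=float)
    if p.shape != (20,):
        raise ValueError("p must have 20 entries")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("p must be a probability distribution")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    ic = float(terms.sum())
    ic = max(ic, 0.0)
    heights = np.where(p > q, p * ic, 0.0)
    return ic, heights


def logo_from_alignment(
    rows: Sequence[str],
    pseudocount_weight: float = 0.0,
    background: np.ndarray | None = None,
    dyad_columns: tuple[int, ...] = (),
) -> LogoTable:
    """Column-wise logo table for a set of aligned rows."""
    if not rows:
        raise ValueError("no rows")
    n_cols = len(rows[0])
    if any(len(r) != n_cols for r in rows):
        raise ValueError("rows differ in length")
    ic = np.zeros(n_cols)
    heights = np.zeros((n_cols, 20))
    occ = np.zeros(n_cols)
    for c in range(n_cols):
        column = "".join(r[c] for r in rows)
        p, occ[c] = column_probabilities(column, pseudocount_weight, background)
        if occ[c] == 0.0:
            continue  # all-gap: IC 0 by convention
        ic[c], heights[c] = information_content(p, background)
    return LogoTable(ic=ic, heights=heights, occupancy=occ, dyad_columns=dyad_columns)


def build_group_logos(
    groups: Mapping[str, Sequence[str]],
    pseudocount_weight: float = 0.0,
    background: np.ndarray | None = None,
    dyad_columns: tuple[int, ...] = (),
    min_rows: int = 2,
) -> dict[str, LogoTable]:
    """One logo table per dyad-motif group (e.g. HC / YS / YN).

    Groups with fewer than ``min_rows`` aligned sequences are skipped with a
    warning.  Dyad columns are flagged in each table for rendering.
    """
    out: dict[str, LogoTable] = {}
    for motif, rows in groups.items():
        if len(rows) < min_rows:
            logger.warning("group %s has %d sequences; skipped", motif, len(rows))
            continue
        out[motif] = logo_from_alignment(
            rows, pseudocount_weight, background, dyad_columns
        )
    return out
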