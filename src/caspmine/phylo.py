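"""Aligned-domain extraction, the survey's pairwise-identity statistic, and
support-based tree pruning.

Pairwise identity is deliberately non-standard: positions inside a terminal
gap run of either sequence are excluded entirely; internal positions gapped
in both sequences are excluded; positions gapped in exactly one sequence
count in the denominator only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .alphabet import GAP_CHARS
from .search import DomainHit


@dataclass
class MSAView:
    """Aligned domain rows with an optional outgroup subset."""

    rows: list[tuple[str, str]]
    outgroup_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        ids = {i for i, _ in self.rows}
        if not self.outgroup_ids <= ids:
            raise ValueError("outgroup_ids must be a subset of row identifiers")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.rows:
                fh.write(f">{name}\n{seq}\n")

    @classmethod
    def from_fasta(
        cls, path: str | Path, outgroup_ids: Iterable[str] = ()
    ) -> "MSAView":
        from Bio import SeqIO

        rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        return cls(rows, set(outgroup_ids))


def extract_trimmed_domains(hits: Sequence[DomainHit]) -> MSAView:
    """Stack per-hit match-column rows and drop all-gap columns.

    Each hit contributes the residues aligned to the profile match columns
    (insertions relative to the profile are discarded, as an aligner's
    trim-to-match-states option would).  Columns that are gaps in every row
    are then removed.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("no hits to extract")
    rows = []
    for h in hits:
        if h.row is None:
            raise ValueError(f"hit on {h.sequence_id} has no aligned row")
        rows.append((h.sequence_id, h.row))
    width = {len(r) for _, r in rows}
    if len(width) != 1:
        raise ValueError("hits come from profiles of different widths")
    arr = np.array([list(s) for _, s in rows])
    keep = ~np.all(np.isin(arr, list(GAP_CHARS)), axis=0)
    trimmed = ["".join(row) for row in arr[:, keep]]
    return MSAView([(name, seq) for (name, _), seq in zip(rows, trimmed)])


def _terminal_gap_mask(row: str) -> np.ndarray:
    """True where a position lies in the maximal gap prefix or suffix."""
    isgap = np.array([c in GAP_CHARS for c in row])
    mask = np.zeros(len(row), dtype=bool)
    i = 0
    while i < len(row) and isgap[i]:
        mask[i] = True
        i += 1
    j = len(row) - 1
    while j >= 0 and isgap[j]:
        mask[j] = True
        j -= 1
    return mask


def pairwise_identity(row_a: str, row_b: str) -> float | None:
    """Fraction of matching positions under the survey's gap conventions.

    Counts a position if it is outside both rows' terminal gap runs and not
    gapped in both rows; a position gapped in exactly one row counts as a
    mismatch.  Returns None when no position is countable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = row_a.upper()
    b = row_b.upper()
    excluded = _terminal_gap_mask(a) | _terminal_gap_mask(b)
    matches = 0
    counted = 0
    for i in range(len(a)):
        if excluded[i]:
            continue
        ga = a[i] in GAP_CHARS
        gb = b[i] in GAP_CHARS
        if ga and gb:
            continue
        counted += 1
        if not ga and not gb and a[i] == b[i]:
            matches += 1
    if counted == 0:
        return None
    return matches / counted


def identity_summary(msa: MSAView) -> tuple[float, float, float, float]:
    """(mean, sd) of percent identity to the outgroup and within the ingroup.

    Means and population standard deviations are taken over all
    ingroup-outgroup pairs and over all unordered ingroup pairs, in percent.
    """
    outgroup = [(n, s) for n, s in msa.rows if n in msa.outgroup_ids]
    ingroup = [(n, s) for n, s in msa.rows if n not in msa.outgroup_ids]
    if len(outgroup) < 1 or len(ingroup) < 2:
        raise ValueError("need >=1 outgroup and >=2 ingroup rows")
    to_out = [
        v
        for _, si in ingroup
        for _, so in outgroup
        if (v := pairwise_identity(si, so)) is not None
    ]
    within = [
        v
        for (_, sa), (_, sb) in combinations(ingroup, 2)
        if (v := pairwise_identity(sa, sb)) is not None
    ]
    if not to_out or not within:
        raise ValueError("no countable positions in one of the pair sets")
    to_out_arr = 100.0 * np.asarray(to_out)
    within_arr = 100.0 * np.asarray(within)
    return (
        float(to_out_arr.mean()),
        float(to_out_arr.std()),
        float(within_arr.mean()),
        float(within_arr.std()),
    )


def identity_summary_frame(msa: MSAView) -> pd.DataFrame:
    mo, so, mi, si = identity_summary(msa)
    return pd.DataFrame(
        {
            "pair_set": ["ingroup_vs_outgroup", "ingroup_vs_ingroup"],
            "mean_identity_pct": [mo, mi],
            "sd_identity_pct": [so, si],
        }
    )


# ---------------------------------------------------------------------------
# Support-based pruning


def read_support_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick tree whose internal node labels are support values."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    return tree


def prune_low_support(tree: dendropy.Tree, threshold: float = 0.85) -> dendropy.Tree:
    """Contract internal edges whose support is below the threshold.

    Children of a weakly supported node are promoted to its parent, forming
    a polytomy; the leaf set is preserved.  Internal node labels are read as
    supports in [0, 1]; unlabeled internal edges are kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    pruned = tree.clone(depth=1)
    to_collapse = []
    for edge in pruned.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None:
            continue
        label = head.label
        if label is None:
            continue
        support = float(label)
        if not (0.0 <= support <= 1.0):
            raise ValueError(f"support {support} outside [0, 1]")
        if support < threshold:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return pruned


def tree_supports(tree: dendropy.Tree) -> list[float]:
    """Supports of all labelled internal (non-root) edges."""
    out = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None or head.label is None:
            continue
        out.append(float(head.label))
    return out
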