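"""Contingency summaries and percentages over classified homolog records."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .classify import round_half_away
from .taxonomy import TaxonTable, group_label

GROUPING_KEYS = ("superkingdom", "group_label", "architecture", "variant", "motif")


def annotate_taxonomy(
    records_frame: pd.DataFrame, table: TaxonTable, rank: str = "phylum"
) -> pd.DataFrame:
    """Add superkingdom and group_label columns resolved from taxids."""
    df = records_frame.copy()
    df["superkingdom"] = [table.superkingdom(t) if t in table.nodes else "unknown"
                          for t in df.taxid]
    df["group_label"] = [group_label(int(t), table, rank=rank) for t in df.taxid]
    return df


def contingency(
    records_frame: pd.DataFrame, grouping: Sequence[str]
) -> pd.DataFrame:
    """Nested counts over one or more grouping keys; partitions the records.

    Grouping keys are columns of the annotated record table: superkingdom,
    group_label, architecture, variant, motif (dyad motif).
    """
    for key in grouping:
        if key not in GROUPING_KEYS:
            raise KeyError(f"unknown grouping key {key!r}")
    df = records_frame.copy()
    if "motif" in grouping:
        df = df.rename(columns={"dyad_motif": "motif"})
    if df.empty:
        return pd.DataFrame(columns=[*grouping, "count"])
    counts = (
        df.groupby(list(grouping), dropna=False, observed=True)
        .size()
        .reset_index(name="count")
        .sort_values(list(grouping), kind="stable")
        .reset_index(drop=True)
    )
    return counts


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float | None:
    """100*num/den, rounded half away from zero; None when undefined."""
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, decimals)
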