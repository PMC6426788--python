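"""Filters and decision tree turning domain hits into classified homologs.

The survey logic: accept sequences whose best p20-domain E-value beats a
threshold, drop sequences with a gap at either catalytic-dyad alignment
column, drop sequences whose p20 envelope length falls outside a
mean +/- 2 sd window, then classify the domain architecture
(paracaspase / metacaspase type I, II, III / orthocaspase / ambiguous) and
call the variant: "true" for an intact His-Cys dyad, "pseudo" for any
substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import GAP
from .search import DomainHit, extract_column_residues

ARCHITECTURES = (
    "paracaspase",
    "metacaspase_I",
    "metacaspase_II",
    "metacaspase_III",
    "orthocaspase",
    "ambiguous",
)

#: Removal reason codes, in the order the filters run.
REMOVAL_REASONS = ("evalue", "dyad_gap", "length", "no_p20_above_cutoff")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the survey's rounding convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and alignment-column assignments for the classifier.

    Score cutoffs are in bits.  ``dyad_columns`` are the profile
    (seed-alignment) columns carrying the catalytic His and Cys;
    ``p10_conserved_columns`` the conserved Cys and Asp of the small
    subunit.  Defaults are the published survey values; dyad columns default
    to the columns of the packaged seed alignments.
    """

    evalue_max: float = 1e-4
    cutoff_p10: float = 30.0
    cutoff_ig: Mapping[str, float] = field(
        default_factory=lambda: {"Ig": 21.8, "Ig_2": 27.0, "Ig_3": 30.0}
    )
    cutoff_p20: float = 35.2
    interdomain_max: int = 66
    length_range: tuple[int, int] = (101, 200)
    dyad_columns: tuple[int, int] = (45, 95)
    p10_conserved_columns: tuple[int, int] = (20, 45)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range lower bound exceeds upper bound")
        if self.interdomain_max < 0:
            raise ValueError("interdomain_max must be non-negative")
        for v in (self.evalue_max, self.cutoff_p10, self.cutoff_p20):
            if not math.isfinite(v):
                raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class DyadCall:
    """Residues observed at the catalytic His and Cys alignment columns."""

    his_residue: str
    cys_residue: str

    @property
    def motif(self) -> str:
        return self.his_residue + self.cys_residue

    @property
    def has_gap(self) -> bool:
        return self.his_residue == GAP or self.cys_residue == GAP


@dataclass
class HomologRecord:
    """One classified caspase homolog."""

    sequence_id: str
    taxid: int
    p20_hits: list[DomainHit]
    p10_hits: list[DomainHit] = field(default_factory=list)
    ig_hits: list[DomainHit] = field(default_factory=list)
    dyad: DyadCall | None = None
    architecture: str | None = None
    variant: str | None = None
    p10_conserved: tuple[str, str] | None = None

    @property
    def best_p20(self) -> DomainHit:
        return max(self.p20_hits, key=lambda h: h.score)


# ---------------------------------------------------------------------------
# Filters and derived thresholds


def filter_by_evalue(
    hits_by_sequence: Mapping[str, Sequence[DomainHit]], evalue_max: float
) -> set[str]:
    """Sequences whose minimum per-domain E-value is strictly below the cap."""
    return {
        sid
        for sid, hits in hits_by_sequence.items()
        if hits and min(h.evalue for h in hits) < evalue_max
    }


def derive_length_range(p20_lengths: Sequence[int]) -> tuple[int, int]:
    """Window of mean +/- 2 sample standard deviations, rounded to integers."""
    if len(p20_lengths) < 2:
        raise ValueError("need at least two domain lengths")
    arr = np.asarray(p20_lengths, dtype=float)
    mean = arr.mean()
    sd = arr.std(ddof=1)
    return (
        int(round_half_away(mean - 2 * sd)),
        int(round_half_away(mean + 2 * sd)),
    )


def derive_p20_cutoff(per_sequence_scores: Mapping[str, Sequence[float]]) -> float:
    """Minimum over sequences of each sequence's maximal p20 bit score."""
    if not per_sequence_scores:
        raise ValueError("no scores supplied")
    maxima = []
    for sid, scores in per_sequence_scores.items():
        if not scores:
            raise ValueError(f"sequence {sid!r} has no scores")
        maxima.append(max(scores))
    return min(maxima)


def derive_interdomain_threshold(
    dists_type_i: Sequence[float], dists_type_ii: Sequence[float]
) -> int:
    """Midpoint between (mean_I + 2 sd_I) and (mean_II - 2 sd_II), rounded.

    The upper 95% bound of short (type I) linkers and the lower 95% bound of
    long (type II) linkers bracket the decision threshold.
    """
    if len(dists_type_i) < 2 or len(dists_type_ii) < 2:
        raise ValueError("need at least two distances per type")
    a = np.asarray(dists_type_i, dtype=float)
    b = np.asarray(dists_type_ii, dtype=float)
    upper_i = a.mean() + 2 * a.std(ddof=1)
    lower_ii = b.mean() - 2 * b.std(ddof=1)
    return int(round_half_away((upper_i + lower_ii) / 2.0))


def call_dyad(p20_hit: DomainHit, dyad_columns: tuple[int, int]) -> DyadCall:
    """Residues at the His and Cys catalytic columns of the p20 alignment."""
    his, cys = extract_column_residues(p20_hit, dyad_columns)
    return DyadCall(his_residue=his, cys_residue=cys)


def label_variant(dyad: DyadCall) -> str:
    """'true' for an intact HC dyad; any substitution makes a 'pseudo' enzyme."""
    if dyad.has_gap:
        raise ValueError("dyad with gaps must be filtered before variant labelling")
    return "true" if dyad.motif == "HC" else "pseudo"


def extract_p10_conserved(
    p10_hit: DomainHit, p10_conserved_columns: tuple[int, int]
) -> tuple[str, str]:
    """Residues at the conserved Cys and Asp columns of the p10 alignment."""
    cys, asp = extract_column_residues(p10_hit, p10_conserved_columns)
    return cys, asp


def classify_architecture(record: HomologRecord, config: ClassifierConfig) -> str:
    """Domain-architecture decision tree.

    Order: multiple p20 or p10 domains -> ambiguous; an Ig-family domain
    starting before the p20 -> paracaspase; a p10 ending before the p20 ->
    metacaspase III; a p10 after the p20 within / beyond the interdomain
    limit -> metacaspase I / II; no p10 -> orthocaspase.  Hits must already
    be thresholded by their per-profile cutoffs.
    """
    if not record.p20_hits:
        raise ValueError("record without a p20 hit should not exist")
    if len(record.p20_hits) > 1 or len(record.p10_hits) > 1:
        return "ambiguous"
    p20 = record.p20_hits[0]
    if any(ig.env_start < p20.env_start for ig in record.ig_hits):
        return "paracaspase"
    if record.p10_hits:
        p10 = record.p10_hits[0]
        if p10.env_end < p20.env_start:
            return "metacaspase_III"
        distance = p10.env_start - p20.env_end - 1
        if p10.env_start > p20.env_start and distance <= config.interdomain_max:
            return "metacaspase_I"
        return "metacaspase_II"
    return "orthocaspase"


# ---------------------------------------------------------------------------
# Pipeline


def _threshold_hits(
    hits: Sequence[DomainHit], cutoff_for: "callable"
) -> list[DomainHit]:
    return [h for h in hits if h.score >= cutoff_for(h)]


def classify_hits(
    hits_by_sequence: Mapping[str, Sequence[DomainHit]],
    taxids: Mapping[str, int],
    config: ClassifierConfig | None = None,
) -> tuple[list[HomologRecord], pd.DataFrame]:
    """Run every filter and the decision tree over per-sequence hit lists.

    ``hits_by_sequence`` maps each sequence id to all its domain hits (p20,
    p10 and Ig-family profiles mixed).  Returns the classified records and a
    removal log with one row per removed sequence (columns: sequence_id,
    reason).  Every input sequence ends either classified or in the log.
    """
    config = config or ClassifierConfig()
    removed: list[tuple[str, str]] = []
    records: list[HomologRecord] = []

    def split(hits: Sequence[DomainHit]):
        p20 = [h for h in hits if h.profile_name == "p20"]
        p10 = [h for h in hits if h.profile_name == "p10"]
        ig = [h for h in hits if h.profile_name in config.cutoff_ig]
        return p20, p10, ig

    for sid in sorted(hits_by_sequence):
        hits = hits_by_sequence[sid]
        p20_all, p10_all, ig_all = split(hits)
        if not p20_all or min(h.evalue for h in p20_all) >= config.evalue_max:
            removed.append((sid, "evalue"))
            continue
        p20 = [h for h in p20_all if h.score >= config.cutoff_p20]
        if not p20:
            removed.append((sid, "no_p20_above_cutoff"))
            continue
        best = max(p20, key=lambda h: h.score)
        dyad = call_dyad(best, config.dyad_columns)
        if dyad.has_gap:
            removed.append((sid, "dyad_gap"))
            continue
        lo, hi = config.length_range
        if not (lo <= best.env_length <= hi):
            removed.append((sid, "length"))
            continue
        p10 = [h for h in p10_all if h.score >= config.cutoff_p10]
        ig = [h for h in ig_all if h.score >= config.cutoff_ig[h.profile_name]]
        rec = HomologRecord(
            sequence_id=sid,
            taxid=int(taxids.get(sid, 0)),
            p20_hits=p20,
            p10_hits=p10,
            ig_hits=ig,
            dyad=dyad,
        )
        rec.architecture = classify_architecture(rec, config)
        if rec.architecture != "ambiguous":
            rec.variant = label_variant(dyad)
            if rec.p10_hits and rec.p10_hits[0].row is not None:
                rec.p10_conserved = extract_p10_conserved(
                    rec.p10_hits[0], config.p10_conserved_columns
                )
        records.append(rec)

    log = pd.DataFrame(removed, columns=["sequence_id", "reason"])
    return records, log


def records_to_frame(records: Iterable[HomologRecord]) -> pd.DataFrame:
    """Flatten classified records into a stable-column-order table."""
    rows = []
    for r in records:
        best = r.best_p20
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "taxid": r.taxid,
                "architecture": r.architecture,
                "variant": r.variant if r.variant is not None else "",
                "dyad_motif": r.dyad.motif if r.dyad else "",
                "p10_cys": r.p10_conserved[0] if r.p10_conserved else "",
                "p10_asp": r.p10_conserved[1] if r.p10_conserved else "",
                "p20_env_start": best.env_start,
                "p20_env_end": best.env_end,
                "p20_score": best.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "taxid",
            "architecture",
            "variant",
            "dyad_motif",
            "p10_cys",
            "p10_asp",
            "p20_env_start",
            "p20_env_end",
            "p20_score",
        ],
    )
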