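"""End-to-end orchestration: calibrate, scan, classify.

Ties the profile search to the classifier so a proteome (in memory or as
FASTA) can be surveyed in one call.  Score calibration is fitted once per
profile on shuffled background decoys at pipeline start.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, HomologRecord, classify_hits, records_to_frame
from .profiles import ProfileModel
from .search import DomainHit, GumbelCalibration, calibrate, search
from .seeds import ig_profile, p10_profile, p20_profile

logger = logging.getLogger(__name__)


def default_profiles() -> list[ProfileModel]:
    return [p20_profile(), p10_profile(), ig_profile()]


def calibrate_profiles(
    profiles: Sequence[ProfileModel],
    length: int = 300,
    n_decoys: int = 1000,
    seed: int = 0,
) -> dict[str, GumbelCalibration]:
    """One Gumbel calibration per profile, from a single seeded stream."""
    rng = np.random.default_rng(seed)
    return {
        p.name: calibrate(p, length=length, n_decoys=n_decoys, rng=rng)
        for p in profiles
    }


def scan_proteome(
    sequences: Sequence[tuple[str, str]],
    profiles: Sequence[ProfileModel],
    calibrations: Mapping[str, GumbelCalibration],
    max_hits: int = 2,
) -> dict[str, list[DomainHit]]:
    """All profile hits for every sequence, keyed by sequence id."""
    out: dict[str, list[DomainHit]] = {}
    for sid, seq in sequences:
        hits: list[DomainHit] = []
        for prof in profiles:
            hits.extend(
                search(
                    prof,
                    seq,
                    calibration=calibrations[prof.name],
                    max_hits=max_hits,
                    sequence_id=sid,
                )
            )
        out[sid] = hits
    return out


def run_survey(
    sequences: Sequence[tuple[str, str]],
    taxids: Mapping[str, int],
    profiles: Sequence[ProfileModel] | None = None,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    n_calibration_decoys: int = 1000,
    max_hits: int = 2,
) -> tuple[list[HomologRecord], pd.DataFrame, dict[str, list[DomainHit]]]:
    """Survey a proteome: returns (records, removal log, raw hits)."""
    profiles = list(profiles) if profiles is not None else default_profiles()
    lengths = [len(s) for _, s in sequences]
    length = int(np.median(lengths)) if lengths else 300
    calibrations = calibrate_profiles(
        profiles, length=length, n_decoys=n_calibration_decoys, seed=seed
    )
    hits = scan_proteome(sequences, profiles, calibrations, max_hits=max_hits)
    records, removal_log = classify_hits(hits, taxids, config)
    logger.info(
        "survey: %d sequences in, %d classified, removals: %s",
        len(sequences),
        len(records),
        dict(removal_log.reason.value_counts()) if len(removal_log) else {},
    )
    return records, removal_log, hits


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
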