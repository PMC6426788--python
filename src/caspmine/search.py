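"""Profile-to-sequence domain search.

The reference aligner is glocal: every profile match column is consumed
exactly once (aligned to a residue or deleted), while the alignment is local
in the sequence.  Gaps are affine and scored in bits, so on a gap-free
alignment the hit score is exactly the sum of the per-column emission
scores.  Statistical significance uses a Gumbel (EVD) tail calibrated on
shuffled decoy sequences, mirroring how profile-HMM engines calibrate
E-values.

Externally produced domain tables (HMMER3 ``--domtblout``) can be ingested
through :func:`read_hmmer_domtbl`; such hits carry no column-to-residue map
and therefore cannot feed alignment-column operations such as catalytic-dyad
extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alphabet import GAP, encode_sequence, uniform_background
from .profiles import ProfileModel

NEG = -1e30  # effectively -infinity in bit space
_MASKED = -1e9  # emission score at masked residues


@dataclass(frozen=True)
class AlignmentMap:
    """Ordered (profile_column, sequence_position) pairs; deletions map to None.

    Profile columns are the source-alignment column indices of the profile's
    match columns; sequence positions are 1-based.
    """

    pairs: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.pairs]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("profile columns must be strictly increasing")
        pos = [p for _, p in self.pairs if p is not None]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("sequence positions must be strictly increasing")

    def position_of(self, column: int) -> int | None:
        for c, p in self.pairs:
            if c == column:
                return p
        raise KeyError(f"column {column} not in alignment map")


@dataclass(frozen=True)
class DomainHit:
    """One detected domain instance on one sequence."""

    sequence_id: str
    profile_name: str
    score: float
    evalue: float
    env_start: int  # 1-based inclusive
    env_end: int
    map: AlignmentMap | None = None
    #: residue (or gap) aligned to each profile match column, in column order;
    #: None for externally ingested hits.
    row: str | None = None

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError("env_start must not exceed env_end")
        if not math.isfinite(self.score):
            raise ValueError("hit score must be finite")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        if self.map is not None:
            for _, p in self.map.pairs:
                if p is not None and not (self.env_start <= p <= self.env_end):
                    raise ValueError("aligned position outside envelope")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class GumbelCalibration:
    """Gumbel tail parameters for converting bit scores to E-values.

    ``pvalue = 1 - exp(-exp(-lam * (score - mu)))``; the E-value is the
    p-value scaled by ``n_comparisons`` (the effective number of independent
    searches, e.g. the database size).
    """

    mu: float
    lam: float
    n_comparisons: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.lam)) or self.lam <= 0:
            raise ValueError("calibration parameters must be finite, lam > 0")

    def pvalue(self, score: float) -> float:
        x = self.lam * (score - self.mu)
        # exp(-x) underflows to 0 for strong hits; -expm1 keeps precision.
        return float(-np.expm1(-np.exp(-min(x, 700.0))))

    def evalue(self, score: float) -> float:
        return self.n_comparisons * self.pvalue(score)


def calibrate(
    profile: ProfileModel,
    length: int = 300,
    n_decoys: int = 1000,
    rng: np.random.Generator | int | None = None,
    n_comparisons: float = 1.0,
) -> GumbelCalibration:
    """Fit the Gumbel tail on best scores of background decoy sequences."""
    rng = np.random.default_rng(rng)
    from .alphabet import AMINO_ACIDS

    aas = np.array(list(AMINO_ACIDS))
    scores = np.empty(n_decoys)
    for k in range(n_decoys):
        seq = "".join(rng.choice(aas, size=length, p=profile.background))
        scores[k] = best_score(profile, seq)
    loc, scale = stats.gumbel_r.fit(scores)
    return GumbelCalibration(mu=float(loc), lam=1.0 / float(scale), n_comparisons=n_comparisons)


def _emission_matrix(profile: ProfileModel, seq_idx: np.ndarray) -> np.ndarray:
    """(n_columns, L) per-position emission scores; ambiguous 'X' scores 0."""
    E = np.where(seq_idx >= 0, profile.emissions[:, np.clip(seq_idx, 0, 19)], 0.0)
    return E


def _forward_matrices(
    E: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill glocal DP matrices M, D, I of shape (C, L) (column-major loop).

    M[j, i]: column j+1 aligned to residue i+1; D[j, i]: columns 1..j+1
    consumed with column j+1 deleted and i+1 residues of prefix used;
    I[j, i]: residue i+1 inserted after column j+1.
    """
    C, L = E.shape
    M = np.full((C, L), NEG)
    D = np.full((C, L), NEG)
    I = np.full((C, L), NEG)
    idx = np.arange(L)

    for j in range(C):
        if j == 0:
            M[0] = E[0]  # fresh local start at column 1
            D[0] = -gap_open  # start, then delete column 1
        else:
            # best predecessor at (i-1, j-1) over M/I/D
            prev = np.maximum(np.maximum(M[j - 1], I[j - 1]), D[j - 1])
            # first residue may still match column j+1 after leading deletions
            M[j, 0] = E[j, 0] - (gap_open + (j - 1) * gap_extend)
            M[j, 1:] = E[j, 1:] + prev[:-1]
            D[j] = np.maximum(M[j - 1] - gap_open, D[j - 1] - gap_extend)
        # I[j, i] = max_{k<i}(M[j, k] - open - (i-1-k)*ext): prefix-scan trick
        run = np.maximum.accumulate(M[j] + idx * gap_extend)
        I[j, 1:] = run[:-1] - gap_open - idx[:-1] * gap_extend
        I[j, 0] = NEG
    return M, D, I


def best_score(profile: ProfileModel, sequence: str) -> float:
    """Best glocal alignment score (bits) without traceback."""
    seq_idx = encode_sequence(sequence)
    E = _emission_matrix(profile, seq_idx)
    M, D, _ = _forward_matrices(E, profile.gap_open, profile.gap_extend)
    return float(max(M[-1].max(), D[-1].max()))


def _traceback(
    profile: ProfileModel,
    E: np.ndarray,
    M: np.ndarray,
    D: np.ndarray,
    I: np.ndarray,
    end_i: int,
    end_state: str,
    sequence: str,
) -> tuple[list[tuple[int, int | None]], str, int, int] | None:
    """Recover the alignment path ending at (end_i, last column, end_state)."""
    go, ge = profile.gap_open, profile.gap_extend
    cols = profile.match_columns
    C = len(cols)
    tol = 1e-6
    pairs: list[tuple[int, int | None]] = []
    row_chars: list[str] = []
    j, i, state = C - 1, end_i, end_state
    first_res = last_res = None
    while True:
        if state == "M":
            pairs.append((cols[j], i + 1))
            row_chars.append(sequence[i])
            if first_res is None or i + 1 < first_res:
                first_res = i + 1
            if last_res is None or i + 1 > last_res:
                last_res = i + 1
            if j == 0:
                break
            if i == 0:  # preceded by a leading-deletion chain
                for jj in range(j - 1, -1, -1):
                    pairs.append((cols[jj], None))
                    row_chars.append(GAP)
                break
            target = M[j, i] - E[j, i]
            j -= 1
            i -= 1
            if abs(M[j, i] - target) < tol:
                state = "M"
            elif abs(D[j, i] - target) < tol:
                state = "D"
            elif abs(I[j, i] - target) < tol:
                state = "I"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in M state")
        elif state == "D":
            pairs.append((cols[j], None))
            row_chars.append(GAP)
            if j == 0:
                break
            if abs(M[j - 1, i] - go - D[j, i]) < tol:
                state = "M"
            elif abs(D[j - 1, i] - ge - D[j, i]) < tol:
                state = "D"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in D state")
            j -= 1
        else:  # I: inserted residue, no map pair
            if abs(M[j, i - 1] - go - I[j, i]) < tol:
                state = "M"
            elif abs(I[j, i - 1] - ge - I[j, i]) < tol:
                state = "I"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in I state")
            i -= 1
    if first_res is None or last_res is None:
        return None  # degenerate: the optimum aligns no residue at all
    pairs.reverse()
    row_chars.reverse()
    return pairs, "".join(row_chars), first_res, last_res


def search(
    profile: ProfileModel,
    sequence: str,
    calibration: GumbelCalibration | None = None,
    max_hits: int = 3,
    sequence_id: str = "seq",
    min_score: float = 0.0,
) -> list[DomainHit]:
    """Find up to ``max_hits`` non-overlapping domain instances in a sequence.

    The best-scoring hit is always reported; further hits are reported while
    their score is at least ``min_score``.  Hits are disjoint: each found
    envelope is masked before searching again.  Without a calibration the
    E-value is reported as ``inf`` ("not assessed").
    """
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    seq_idx = encode_sequence(sequence)
    E0 = _emission_matrix(profile, seq_idx)
    masked = np.zeros(len(sequence), dtype=bool)
    hits: list[DomainHit] = []
    for k in range(max_hits):
        E = E0.copy()
        if masked.any():
            E[:, masked] = _MASKED
        M, D, I = _forward_matrices(E, profile.gap_open, profile.gap_extend)
        final = np.maximum(M[-1], D[-1])
        end_i = int(final.argmax())
        score = float(final[end_i])
        if score <= NEG / 2 or (k > 0 and score < min_score):
            break
        end_state = "M" if M[-1, end_i] >= D[-1, end_i] else "D"
        traced = _traceback(profile, E, M, D, I, end_i, end_state, sequence)
        if traced is None:
            break
        pairs, row, start, end = traced
        ev = calibration.evalue(score) if calibration is not None else float("inf")
        hits.append(
            DomainHit(
                sequence_id=sequence_id,
                profile_name=profile.name,
                score=score,
                evalue=ev,
                env_start=start,
                env_end=end,
                map=AlignmentMap(tuple(pairs)),
                row=row,
            )
        )
        masked[start - 1 : end] = True
    hits.sort(key=lambda h: h.score, reverse=True)
    return hits


def extract_column_residues(
    hit: DomainHit, columns: Sequence[int]
) -> tuple[str, ...]:
    """Residue (or '-') aligned to each requested profile column, in order.

    Columns are source-alignment column indices, i.e. entries of the
    profile's ``match_columns``.  Requires a hit with an alignment map.
    """
    if hit.map is None or hit.row is None:
        raise ValueError("hit carries no alignment map (external hit?)")
    col_to_idx = {c: k for k, (c, _) in enumerate(hit.map.pairs)}
    out = []
    for col in columns:
        if col not in col_to_idx:
            raise KeyError(f"column {col} is not a match column of {hit.profile_name}")
        out.append(hit.row[col_to_idx[col]])
    return tuple(out)


# ---------------------------------------------------------------------------
# Hit-table I/O

HIT_COLUMNS = ["sequence_id", "profile", "score", "evalue", "env_start", "env_end"]


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (h.sequence_id, h.profile_name, h.score, h.evalue, h.env_start, h.env_end)
            for h in hits
        ],
        columns=HIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        DomainHit(
            sequence_id=str(r.sequence_id),
            profile_name=str(r.profile),
            score=float(r.score),
            evalue=float(r.evalue),
            env_start=int(r.env_start),
            env_end=int(r.env_end),
        )
        for r in df.itertuples()
    ]


def read_hmmer_domtbl(path: str | Path) -> list[DomainHit]:
    """Ingest a HMMER3 ``--domtblout`` file as DomainHit records.

    Uses the per-domain (independent) E-value, the domain bit score and the
    envelope coordinates.  The alignment map is not recoverable from the
    table and is left unset.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            hits.append(
                DomainHit(
                    sequence_id=f[0],
                    profile_name=f[3],
                    score=float(f[13]),
                    evalue=float(f[12]),
                    env_start=int(f[19]),
                    env_end=int(f[20]),
                )
            )
    return hits
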