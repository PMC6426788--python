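"""Glocal profile search: oracle equivalence, planted recovery, statistics."""

import functools
import math

import numpy as np
import pytest

from caspmine.alphabet import AA_INDEX, AMINO_ACIDS
from caspmine.profiles import SeedAlignment, build_profile
from caspmine.search import (
    DomainHit,
    GumbelCalibration,
    best_score,
    calibrate,
    extract_column_residues,
    read_hmmer_domtbl,
    search,
)


def enumerate_best_score(profile, sequence: str) -> float:
    """Independent oracle: exhaustive recursion over the alignment state
    machine (match/delete/insert with affine gaps, all columns consumed,
    local in the sequence)."""
    e = profile.emissions
    go, ge = profile.gap_open, profile.gap_extend
    C = profile.n_columns
    seq = [AA_INDEX[c] for c in sequence]
    L = len(seq)
    NEG = float("-inf")

    @functools.lru_cache(maxsize=None)
    def rec(j: int, i: int, state: str) -> float:
        if j == C:
            return 0.0 if state in ("M", "D") else NEG
        out = NEG
        if i < L:  # match column j with residue i
            out = max(out, e[j, seq[i]] + rec(j + 1, i + 1, "M"))
        if state in ("M", "S"):  # open a deletion
            out = max(out, -go + rec(j + 1, i, "D"))
        elif state == "D":  # extend a deletion
            out = max(out, -ge + rec(j + 1, i, "D"))
        if i < L and state == "M":  # open an insertion
            out = max(out, -go + rec(j, i + 1, "I"))
        elif i < L and state == "I":  # extend an insertion
            out = max(out, -ge + rec(j, i + 1, "I"))
        return out

    result = max(rec(0, i0, "S") for i0 in range(L + 1))
    rec.cache_clear()
    return result


def random_profile(rng, n_cols: int):
    rows = tuple(
        (f"r{i}", "".join(rng.choice(list(AMINO_ACIDS), n_cols)))
        for i in range(4)
    )
    return build_profile(SeedAlignment(rows), 1, n_cols, name="rand")


@pytest.mark.parametrize("trial", range(30))
def test_search_matches_exhaustive_enumeration(trial):
    """On tiny instances the DP equals brute-force enumeration of all
    glocal alignments (score to 1e-9 bits)."""
    rng = np.random.default_rng(100 + trial)
    n_cols = int(rng.integers(2, 7))
    n_res = int(rng.integers(1, 16))
    prof = random_profile(rng, n_cols)
    seq = "".join(rng.choice(list(AMINO_ACIDS), n_res))
    expected = enumerate_best_score(prof, seq)
    got = best_score(prof, seq)
    assert got == pytest.approx(expected, abs=1e-9)
    hits = search(prof, seq, max_hits=1)
    if hits:
        assert hits[0].score == pytest.approx(expected, abs=1e-9)
    else:
        # optimum aligns no residue: it must be the pure-deletion score
        pure_deletion = -prof.gap_open - (prof.n_columns - 1) * prof.gap_extend
        assert expected == pytest.approx(pure_deletion, abs=1e-9)


def test_self_hit_score_is_sum_of_consensus_emissions(tiny_profile):
    cons = tiny_profile.consensus()
    hit = search(tiny_profile, cons, max_hits=1)[0]
    assert hit.score == pytest.approx(tiny_profile.consensus_score(), abs=1e-9)
    assert (hit.env_start, hit.env_end) == (1, len(cons))
    assert all(p is not None for _, p in hit.map.pairs)
    # score additivity on the gap-free alignment
    total = sum(
        tiny_profile.emissions[k, AA_INDEX[hit.row[k]]]
        for k in range(tiny_profile.n_columns)
    )
    assert hit.score == pytest.approx(total, abs=1e-9)


def test_planted_consensus_envelope_recovered_exactly():
    from caspmine.seeds import p20_profile

    prof = p20_profile()
    rng = np.random.default_rng(5)
    cons = prof.consensus()
    flank = lambda n: "".join(rng.choice(list(AMINO_ACIDS), n))
    seq = flank(50) + cons + flank(40)
    hit = search(prof, seq, max_hits=1)[0]
    assert (hit.env_start, hit.env_end) == (51, 50 + len(cons))
    assert hit.row == cons


@pytest.mark.parametrize("trial", range(10))
def test_appending_unrelated_residues_never_decreases_score(trial):
    rng = np.random.default_rng(300 + trial)
    prof = random_profile(rng, int(rng.integers(3, 7)))
    seq = "".join(rng.choice(list(AMINO_ACIDS), int(rng.integers(5, 20))))
    base = best_score(prof, seq)
    left = "".join(rng.choice(list(AMINO_ACIDS), 5)) + seq
    right = seq + "".join(rng.choice(list(AMINO_ACIDS), 5))
    assert best_score(prof, left) >= base - 1e-9
    assert best_score(prof, right) >= base - 1e-9


def test_multiple_hits_are_non_overlapping(tiny_profile):
    cons = tiny_profile.consensus()
    seq = cons + "KKKKKKKKKK" + cons
    hits = search(tiny_profile, seq, max_hits=3, min_score=1.0)
    assert len(hits) >= 2
    spans = sorted((h.env_start, h.env_end) for h in hits[:2])
    assert spans[0][1] < spans[1][0]


def test_illegal_characters_rejected(tiny_profile):
    with pytest.raises(ValueError):
        search(tiny_profile, "ACDB!", max_hits=1)
    with pytest.raises(ValueError):
        search(tiny_profile, "", max_hits=1)


def test_extract_column_residues_and_gap_flag(tiny_profile):
    cons = tiny_profile.consensus()  # AHCDE; dyad at columns 2 and 3
    hit = search(tiny_profile, cons, max_hits=1)[0]
    assert extract_column_residues(hit, [2, 3]) == ("H", "C")
    # planted substituted dyad
    hit2 = search(tiny_profile, "AYSDE", max_hits=1)[0]
    assert extract_column_residues(hit2, [2, 3]) == ("Y", "S")
    with pytest.raises(KeyError):
        extract_column_residues(hit, [99])


def test_deleted_column_reported_as_gap(tiny_profile):
    # residue at the His column removed: best alignment deletes one column
    hit = search(tiny_profile, "ACDE", max_hits=1)[0]
    residues = extract_column_residues(hit, [2, 3])
    assert "-" in residues


def test_gumbel_evalue_monotone_and_calibration(tiny_profile):
    cal = calibrate(tiny_profile, length=30, n_decoys=200, rng=0, n_comparisons=1.0)
    assert cal.evalue(cal.mu) == pytest.approx(1 - math.exp(-1), rel=1e-6)
    scores = [0.0, 5.0, 10.0, 20.0]
    evs = [cal.evalue(s) for s in scores]
    assert all(a >= b for a, b in zip(evs, evs[1:]))
    assert all(ev >= 0 for ev in evs)
    # a strong self-hit is extremely significant
    strong = search(tiny_profile, tiny_profile.consensus() * 3, cal, max_hits=1)[0]
    assert strong.evalue < 1e-3


def test_hmmer_domtbl_adapter(tmp_path):
    text = (
        "# comment line\n"
        "seqA - 400 p20 - 150 1e-50 300.0 0.1 1 1 1e-48 "
        "1e-45 290.0 0.2 5 140 10 160 8 165 0.9\n"
    )
    path = tmp_path / "hits.domtbl"
    path.write_text(text)
    hits = read_hmmer_domtbl(path)
    assert len(hits) == 1
    h = hits[0]
    assert (h.sequence_id, h.profile_name) == ("seqA", "p20")
    assert (h.env_start, h.env_end) == (8, 165)
    assert h.score == pytest.approx(290.0)
    assert h.map is None


def test_pyhmmer_finds_planted_domains(small_proteome):
    """Cross-check with an independent profile-HMM engine: an HMM built from
    the same seed alignment locates the planted p20 domains at overlapping
    coordinates."""
    pyhmmer = pytest.importorskip("pyhmmer")
    from caspmine.seeds import p20_seed

    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(name=n.encode(), sequence=s)
        for n, s in p20_seed().rows
    ]
    msa = pyhmmer.easel.TextMSA(name=b"p20", sequences=seqs).digitize(alphabet)
    hmm, _, _ = pyhmmer.plan7.Builder(alphabet).build_msa(
        msa, pyhmmer.plan7.Background(alphabet)
    )
    targets = [
        pyhmmer.easel.TextSequence(name=n.encode(), sequence=s).digitize(alphabet)
        for n, s in small_proteome.sequences
    ]
    results = {
        str(h.name): h
        for tophits in pyhmmer.hmmsearch([hmm], targets, E=1e-5)
        for h in tophits
    }
    planted = small_proteome.truth[small_proteome.truth.architecture != "decoy"]
    found = 0
    for row in planted.itertuples():
        h = results.get(row.sequence_id)
        if h is None:
            continue
        dom = h.best_domain
        overlap = min(dom.env_to, row.p20_end) - max(dom.env_from, row.p20_start)
        if overlap > 0.5 * (row.p20_end - row.p20_start + 1):
            found += 1
    assert found >= 0.95 * len(planted)
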