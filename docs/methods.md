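# Methods

## The problem

Caspase-family proteases (MEROPS clan CD, family C14) are defined by a
catalytic p20 domain with a His–Cys dyad. In prokaryotes the family splits
into architectures: **orthocaspases** (p20 only), **metacaspases** (p20 plus
a small p10 subunit — type I with a short linker, type II with a long
linker, type III with the p10 N-terminal to the p20) and **paracaspases**
(immunoglobulin-like domain(s) preceding the p20). Homologs whose dyad
carries substitutions (Tyr–Ser being the most common) are presumed
proteolytically inactive and are called **pseudo**-variants; those with an
intact His–Cys dyad are **true**-variants.

`caspmine` implements the full mining-and-classification procedure as a
reusable, tested pipeline: profile construction and domain search, survey
filters, the architecture decision tree, variant calling, taxonomy
grouping, a non-standard pairwise-identity statistic, support-based tree
pruning, above-background sequence logos, and a synthetic-proteome
generator that makes every stage testable at desk scale without any
database download.

## Profile model and search

A profile is built from a column slice of a seed alignment. Columns with
residue occupancy ≥ 50% become match columns (the standard profile
construction heuristic). Column probabilities are pseudocount-smoothed
toward a background distribution q,

    p_a = (c_a + w·q_a) / (n + w),        emission_a = log2(p_a / q_a)  [bits]

with pseudocount weight w = 1 by default. The background defaults to
uniform (1/20); real amino-acid compositions can be supplied.

The reference aligner is **glocal**: global over the profile's match
columns (each consumed exactly once, either aligned to a residue or
deleted) and local in the sequence. Gaps are affine, default
`gap_open = 4` bits and `gap_extend = 0.25` bits, with the Plan7
convention that insert and delete states do not interconvert. On a
gap-free alignment the hit score is exactly the sum of the per-column
emissions. The DP is vectorised over sequence positions with a
prefix-scan for the insert state, and is verified against an independent
exhaustive enumeration of all alignments on small instances. Multiple
domain instances per sequence are found by masking each reported envelope
and re-running the DP; reported hits are therefore disjoint.

E-values use a Gumbel (extreme-value) tail, `P(S > s) =
1 − exp(−exp(−λ(s−µ)))`, with µ and λ fitted (scipy `gumbel_r`) on the
best scores of 1,000 seeded background decoy sequences at pipeline start —
the same scheme profile-HMM engines use, calibrated per profile. Full
Plan7 semantics (forward-algorithm E-values, posterior envelopes) are out
of scope; externally produced HMMER3 `--domtblout` tables can be ingested
through an adapter, though such hits carry no column-to-residue map and
cannot feed dyad extraction.

## Packaged seed alignments

Curated family seeds cannot be redistributed here, so the package ships
**synthetic** seed alignments generated deterministically from a fixed
internal seed: a p20-like seed (150 columns, 40 rows, 5% per-site row
substitution, invariant His at column 45 and Cys at column 95), a p10-like
seed (60 columns, conserved Cys at 20 and Asp at 45) and an Ig-like seed
(70 columns). The catalytic/conserved column indices are known by
construction and serve as the classifier defaults; with a real family
seed, the dyad columns are configurable and should be obtained by mapping
an annotated reference sequence through the alignment.

## Survey filters and classification

Filters run in the published order, and every input sequence ends either
classified or in a removal log with a reason code:

1. **E-value**: a sequence survives iff its best (minimum) per-domain p20
   E-value is *strictly* below 1e-4.
2. **Dyad gap**: sequences whose best p20 alignment has a gap at the His
   or Cys column are removed.
3. **Length window**: the p20 envelope length must fall within 101–200
   residues (the published mean ± 2 sd window). `derive_length_range`
   recomputes such a window (sample sd, n−1) from any length set.
4. **Score cutoffs**: per-profile bit-score cutoffs — p10 30.0, Ig 21.8,
   Ig_2 27.0, Ig_3 30.0, and p20 35.2. The p20 cutoff's derivation rule
   (minimum over sequences of the per-sequence maximal p20 score) is
   implemented as `derive_p20_cutoff`.

The architecture decision tree, in precedence order: more than one p20 or
p10 above cutoff → *ambiguous*; any Ig-family hit starting before the p20
→ *paracaspase*; a p10 ending before the p20 start → *metacaspase III*;
a p10 starting after the p20 start at an interdomain distance
(`p10_start − p20_end − 1`; overlaps count as short) of at most 66
residues → *type I*, otherwise *type II*; no p10 → *orthocaspase*.
The 66-residue limit is the midpoint between (mean + 2 sd) of type I and
(mean − 2 sd) of type II interdomain distances (`derive_interdomain_threshold`);
66 is the shipped default since the underlying published distance sets are
external. Precedence among conflicting evidence (e.g. a qualifying Ig and
a qualifying p10) is not fully pinned down in the source procedure; the
ambiguity test runs first, then paracaspase, then metacaspase typing.

Variant labels: *true* iff the dyad motif is exactly HC; any substitution,
single or double, is *pseudo*. Conserved p10 Cys/Asp residues are
extracted for metacaspases but trigger no removal.

Derived integer thresholds round half away from zero.

## Taxonomy

NCBI-style taxdump files (`nodes.dmp`/`names.dmp`, pipe-tab dialect) are
loaded into a validated table (single root, no orphans, acyclic). The
survey's group label is the phylum, except Proteobacteria which resolve to
their class; order-level labels are available via a rank parameter.
Unresolvable taxids are labelled "unknown" with a logged warning.

## Pairwise identity, alignment views, tree pruning

Aligned p20 rows are obtained from hits by keeping only match-column
residues (insertions dropped, as an aligner's trim option would) and
removing columns that are gaps in every row.

The identity statistic is deliberately non-standard: positions inside a
terminal gap run of either row are excluded entirely; internal positions
gapped in *both* rows are excluded; positions gapped in exactly one row
count in the denominator only; matches require identical residues. Group
summaries report mean and (population) sd over all ingroup–outgroup pairs
and over all unordered ingroup pairs, in percent.

Support pruning contracts every internal edge whose support is below the
threshold (default 0.85), promoting its children into a polytomy. This
preserves the full leaf set — matching figure captions that count all
sequences — and is idempotent. The alternative reading (deleting subtrees)
was rejected for that reason.

## Sequence logos

Per column, smoothed residue frequencies p are compared with the
background q by relative entropy, `IC = Σ p_a log2(p_a/q_a)` bits; letter
heights are `p_a·IC` for letters enriched above background (p_a > q_a) and
zero otherwise. Gaps reduce a column's occupancy but carry no probability
mass; an all-gap column has occupancy 0 and IC 0. This is a documented
approximation of web-service logo renderers, whose exact height rule for
"above background" displays is not published; both alignment frequencies
and profile match-state probabilities can be fed in.

## Synthetic proteomes

The generator emulates the statistical structure the classifier assumes,
with defaults chosen to mirror the surveyed population:

| parameter | default | rationale |
|---|---|---|
| p20 envelope length | Normal(150.5, 24.75), truncated to [101, 200] | mean ± 2 sd reproduces the 101–200 window |
| type I linker | Normal(20, 10) aa, truncated to ≤ 66 | short-linker regime; class-defining |
| type II linker | Normal(120, 10) aa, truncated to ≥ 67 | long-linker regime; the bracket midpoint is ~70 |
| dyad motifs | HC .914, YS .030, YN .020, YG .010, QC .008, HA .008, FS .010 | ~8.6% pseudo mass, YS the most common substitution |
| class counts (per 1,000) | 700 ortho, 80 type I, 40 type II, 30 type III, 30 para, 20 ambiguous, 100 decoys | orthocaspase-dominated, ~10% metacaspases |
| mutation rate | 0 (configurable) | per-site substitution applied to planted domains |

Domains are planted from the profile consensus. Envelope lengths are
realised as *scattered* single-column deletions (lengths below the profile
width) or scattered background insertions (lengths above it); the
catalytic stretch (dyad ± 5 columns) and both terminal anchor regions
(columns 1–19 and 146–150) stay indel-free. Scattering matters: contiguous
deletion blocks would let the optimal alignment trade block deletions for
chance matches in the flanking sequence, extending envelopes far beyond
the plant; with interleaved consensus anchors such rearrangements are
strictly unprofitable and planted envelopes are recovered essentially
exactly in the noise-free case. Dyad columns are overwritten with the
drawn motif *after* mutation, so a planted motif is always observable.
Decoys are drawn from the background composition with lengths resampled
from the planted sequences, keeping the E-value filter meaningful. A
single generator RNG seeded once drives every draw; identical specs give
byte-identical FASTA.

What the generator does **not** emulate: evolutionary correlation between
sequences (no phylogeny), indel processes beyond the length model,
compositional bias, and real seed-alignment diversity. Passing the
recovery tests therefore demonstrates the correctness of the pipeline's
logic and thresholds under the stated statistical conditions, not search
sensitivity on real proteomes.

## Numerical and degenerate-input choices

Scores are bits throughout; score ties in the DP resolve
deterministically (match preferred over deletion at the terminal column).
An alignment whose optimum contains no matched residue reports no hit.
Zero-denominator percentages and identity over zero countable positions
report as missing rather than raising. Thresholds are compared with the
exact inequalities stated above (strict for the E-value filter, inclusive
for score cutoffs and the interdomain limit).

## Problem sizes

The test suite and the acceptance script run the classifier on
1,000-sequence proteomes (900 planted + 100 decoys) with 1,000-decoy
score calibration per profile, oracle comparisons on profiles of ≤ 6
columns, 1,000 random identity pairs, and 2,000-sequence motif-frequency
checks — sizes at which every check completes in seconds to a few minutes
on one CPU.

## Known limitations

- The aligner is a reference implementation of the search contract, not a
  full profile HMM; absolute bit scores and E-values are not comparable
  with HMMER's. The published 35.2-bit cutoff is kept as a config default
  for fidelity, but on synthetic profiles the derived cutoff is
  scale-dependent.
- Full-scale published claims (11,208 homologs, the Figure-level identity
  summaries such as 9.6% ± 2.0 to the outgroup) depend on a UniProt-scale
  search and are documented, not asserted, here.
- Accessory-domain annotation (TPR, trypsin-like, DUF4384, …) is limited
  to running extra user-supplied profiles through the same engine.
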