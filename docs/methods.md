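# Methods

## Model and procedure

zonescan performs heuristic local protein similarity search as a pipeline
of accumulators and filters of increasing cost: direct-addressed k-tuple
lookup, diagonal similarity-zone accumulation, zone clustering, banded
affine-gap local alignment, and Karlin–Altschul statistics. The guiding
assumption is that biologically meaningful local alignments are anchored by
clusters of near-exact k-tuple matches on a small bundle of adjacent
diagonals; seed matches that never accumulate into a dense zone are
discarded before any DP is computed.

### Residues, tuples and scores

Sequences are mapped to integer indices over the 20 standard amino acids in
the order of the bundled matrix header (`ARNDCQEGHILKMFPSTWYV`). A k-tuple
is encoded base-20, most significant residue first; the code doubles as the
address into the lookup table. Non-standard letters (B, Z, X, U, O, J, `*`)
are retained in the sequence but any k-tuple window containing one
contributes no seeds, on either the query or the subject side; during
alignment such residues score the matrix minimum. Rationale: no published
matrix defines principled scores for ambiguity codes, and skipping windows
cannot create false seeds.

Substitution matrices are parsed from NCBI text format and validated for
symmetry and for the self-score dominating each row. The latter is not
cosmetic: it is the admissibility condition for the branch-and-bound used
in diversification.

### Tuple diversification

The neighborhood of an occurring query tuple t is
`{t' : score(t', t) >= approx * score(t, t)}` with `approx` in (0, 1]. The
ratio's denominator is the *query* tuple's self score. Integer match scores
are compared against the real-valued threshold directly — no rounding — so
ties at the threshold are included. Enumeration proceeds level-by-level
over prefixes held in numpy arrays: at level p every surviving prefix is
extended by all 20 residues and pruned with the bound
`prefix_score + self_suffix_score(p+1) < threshold`. This is an iterative
realisation of the depth-first trie walk; results come out in increasing
code order, which makes table construction deterministic.

### Lookup table

Built in two passes so a single contiguous entry arena can be allocated
exactly: pass 1 counts exact occurrences per code and credits each
occurring code's count to every neighbor (a code is always its own
neighbor); pass 2 re-runs diversification and copies locations with their
suffix-score vectors into the neighbors' regions. Diversification is
recomputed rather than cached between passes, keeping peak memory bounded
by the final table. Tuples per query of length L occupy positions
0..L−k inclusive (L−k+1 windows). Each entry stores the k suffix match
scores of the diversified key tuple against the originating query tuple;
at search time an overlap of o residues with the previous match on a
diagonal contributes `suffix_scores[o]` without any matrix access.

### Zone accumulation

Diagonals are indexed by `query_global_offset − subject_offset +
max_subject_len`; the diagonal array has `total_query_length +
max_subject_len` entries. Diagonal entries are invalidated lazily by
storing the subject ordinal (and query index) they were last used with:
state is trusted only when both match the current context, so no per-subject
clearing is needed. Zone and hits arenas are preallocated (2,000,000 and
65,536 by default) with fill counters reset per subject; exhaustion logs a
warning and degrades gracefully.

A match on a diagonal either starts a zone (fresh/stale/different-query
entry) seeded with the full-tuple match score, or attempts to extend the
diagonal's active zone: `extended = zone_score + incremental − gap`, where
the incremental score is the suffix score for the overlap and same-diagonal
separations d > k pay `gip + gep * (d − k)`. Non-positive extensions start
a fresh zone; the previous zone stays active (and stays in the hits array
if it was recorded). After each update, up to `mxshift` diagonals on each
side are searched for merge partners; a merge is accepted when the
overlap-adjusted score sum exceeds the affine penalty on the diagonal
distance, the lower-indexed zone survives with union bounds, and the
loser's diagonal entries (and hits-array slot, if the survivor has none)
are re-pointed.

Overlap adjustment, here and in clustering: when two zones' subject
intervals overlap by v residues, the shorter zone's score is scaled by
`1 − v / its_length` before summation. The linear proration is this
package's choice; it makes a fully contained zone contribute nothing new
while barely touching genuinely collinear zones.

A zone enters the hits array the first time its updated running score
reaches `kthresh` (sentinel-guarded, so exactly once), and remains listed
even if its score later drops. After the subject is consumed, single-linkage
clustering links zones of the same query whose adjusted score sum exceeds
the affine penalty on the minimal *diagonal* distance between them; note
that collinear zones on the same diagonal therefore always link, however
far apart along the subject — the gap is charged later, in alignment or
chaining, not at the linking step. Components merge into their
lowest-indexed member with union bounds; the merged score chains members in
subject order (prorated, minus the diagonal-distance penalties).

### Banded alignment

Merged zones are widened by `band_extension` (default 16 residues: half the
extension on each side of the diagonal span, the full extension along the
diagonal both ways, clipped to the sequences) and aligned with a
three-state (match / gap-in-query / gap-in-subject) affine local DP
restricted to the band. A gap of length L costs `gip + gep * L`. Cells
outside the band are unreachable; storage is rows x band-width. The DP
reports the maximal local alignment with traceback; tie-breaks are fixed —
earliest best end cell in (subject, query) scan order, diagonal preferred
over gap-in-query over gap-in-subject — making output deterministic. The
banded-NW-with-SW-scores formulation described for the original is
ambiguous between a global-in-band pass and a direct local DP; this package
implements the direct banded local DP.

One band may contain several similarity segments separated by stretches a
local alignment will not cross (long gaps, strongly dissimilar middles).
After the best alignment is extracted, the band is split at its subject
span and the remainders are aligned recursively; secondary alignments are
kept when they reach `kthresh`. This multiple-HSP extraction is what makes
repeat and multi-domain similarities visible to the downstream filters.

### Post-processing and statistics

Pipeline order is fixed: align → score filter → repeat filter → optional
remote merge → statistics → rank. Filters never alter an alignment's
coordinates or score.

The repeat filter groups alignments of one query/subject pair that overlap
by at least 50% of the shorter interval on one sequence while being
disjoint on the other (transitively closed) and keeps each group's best
scorer. The 50% fraction is this package's threshold. The remote merger
(off by default) chains collinear segments by DP: segment j may follow i
only if both intervals advance, the bridge costs
`affine_gap_penalty(max(q_gap, s_gap))`, and a link is taken only when it
beats leaving the downstream segment alone; chains partition the segments.
With the default gap penalties the merger pays off only for moderate
bridges (up to roughly the segment score); segments separated by very long
gaps stay separate, as they should.

E-values use `E = K * m * n * exp(−lambda * S)` with m the query length and
n the total residue count of the subject database (BLAST convention; no
edge-effect correction). For (BLOSUM62, 11, 1) the published gapped pair
(lambda = 0.267, K = 0.041) is bundled; any other combination falls back,
with a logged warning, to the exact ungapped lambda — the unique positive
root of `sum p_i p_j exp(lambda s_ij) = 1`, solved by Brent's method to a
residual below 1e−9 — and a coarse K estimate. Background frequencies
default to uniform 1/20 (deterministic and dataset-independent); the
Robinson–Robinson composition is available and reproduces the canonical
ungapped BLOSUM62 lambda of 0.3176. E-values therefore rank correctly but
are not numerically interchangeable with SSEARCH's — a documented
limitation. Ranking is by ascending E-value (ties: descending score, then
subject id), truncated to `rpq`, with a report-time E-value cutoff
(default 10).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `ksize` (k) | 5 | residues | seed tuple length; 3..6 (the 20^k table must fit memory) |
| `approx` | 0.85 | fraction | diversification threshold; the dominant speed/sensitivity dial |
| `kthresh` | 18 | score units | zone score triggering downstream processing; correlates with specificity |
| `mxshift` | 3 | diagonals | lateral merge reach; sensitivity saturates around 3–4 |
| `gip`, `gep` | 11, 1 | score units | affine gap penalties (standard BLOSUM62 pairing) |
| `max_subject_len` | 50,000 | residues | diagonal-array sizing; longer subjects are an error |
| `band_extension` | 16 | residues | band widening before alignment |
| `rpq` | 100 | hits | results kept per query |
| `max_evalue` | 10 | — | report threshold |
| zone / hits arenas | 2,000,000 / 65,536 | — | preallocated capacity; exhaustion warns, never aborts |

Defaults for `kthresh`, `approx` and `mxshift` sit in the parameter region
where the method's coverage-to-error behavior is strongest; `approx` is the
knob to move first in either direction.

## Synthetic data

The generator emulates the search-relevant structure of real data: i.i.d.
residue composition (uniform default, Robinson option), point substitutions
at a per-residue rate, geometric-length indels (rate-driven or exact
counts), tandem repeats and two-domain fusions with known coordinates, and
the planted-homolog benchmark (300-residue query, 20% substitutions, one
insertion plus one deletion, 50 decoys). It does not emulate real protein
statistics beyond composition: no position-dependent conservation, domain
architecture, low-complexity regions or evolutionary rate variation.
Passing tests therefore demonstrate algorithmic correctness (oracle
equivalence, recall under the stated mutation model, determinism), not
field sensitivity on natural proteomes.

## Numerical choices and degenerate inputs

Integer scores throughout seeding; statistics in floats. Threshold
comparisons against `approx * self_score` are exact real comparisons with
ties included. Queries shorter than k contribute nothing; an empty query
set is an error, an empty subject set is a valid empty search. Degenerate
(empty-after-clipping) bands align to nothing. Duplicate alignments
rediscovered from overlapping bands of distinct zones are deduplicated per
query/subject pair by coordinates and score.

## Problem sizes used in validation

Stage oracles run at sizes where exhaustive computation is exact and quick:
diversification against all 3,200,000 codes for 50 tuples x 4 thresholds;
table construction against a brute-force index at k = 3 (8,000 codes,
20 x 300-residue queries); banded vs full Smith–Waterman on 100 pairs of
length ≤ 200; planted-homolog recall over 100 trials. These sizes are the
package's validation conditions and are fixed in the acceptance script.

## Known limitations

- E-values are internally consistent but not calibrated against
  SSEARCH/BLAST beyond the bundled (BLOSUM62, 11, 1) pair.
- No weighted (frequency-based) k-tuple scoring.
- No gapped tuple matches, subject-side indexing, persisted indexes,
  composition-based statistics, SIMD inner loops, or multithreading.
- The TEXT output format is a readable rendering, not a replica of any
  other tool's layout.
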