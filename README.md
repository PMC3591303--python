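# zonescan

Fast seed-and-extend protein similarity search for large query batches:
index a query protein set once with *diversified k-tuples*, stream a
subject FASTA against it, aggregate seed matches into *diagonal similarity
zones*, align merged zones with a banded affine-gap local DP, and report
E-value-ranked hits in BLAST-like tabular formats.

The tool targets the common annotation scenario — screening thousands of
predicted proteins against a large database for relatively strong
homologies — where exhaustive Smith–Waterman or even default BLASTP is
slower than necessary and a controlled sensitivity/speed trade-off is
acceptable.

## Method

**Lookup table.** Every k-tuple (default k = 5) occurring in the query set
is *diversified*: the set `{t' : score(t', t) >= approx * score(t, t)}` of
all sufficiently similar tuples is enumerated by a depth-first walk of the
20-way, k-level tuple trie, pruning any branch whose prefix score plus the
best possible (self-matching) suffix falls below the threshold. Pruning is
safe because the self-match score dominates every substitution-matrix row
(validated at load; BLOSUM62 bundled by default). Locations are stored in a
direct-addressed table over all 20^k codes — the base-20 encoded tuple *is*
the address — built in two passes (count, then fill) into one exactly
partitioned entry arena. Each entry carries precomputed suffix match
scores, so overlapping seed matches are scored at search time without
touching the matrix.

**Similarity zones.** Each subject position's k-tuple is looked up and
every match lands on a diagonal of the query-concatenation x subject
similarity matrix. Per-diagonal state (last match offset, running score,
zone reference, subject ordinal) is kept in flat arrays with lazy
invalidation — nothing is cleared between subjects. Matches extend the
diagonal's zone (overlap-corrected via suffix scores, gaps charged with the
affine penalty `gip + gep * L`), or start a fresh zone when extension is
unprofitable. After each match, up to `mxshift` adjacent diagonals are
searched for zones to merge. Zones whose running score reaches `kthresh`
enter the hits array once; after the subject is consumed, single-linkage
clustering joins compatible zones separated by longer gaps.

**Alignment and statistics.** Each merged zone is widened by
`band_extension` and aligned with a three-state affine banded local DP
(memory and time proportional to band area, never m x n). Score and repeat
filters, and an optional remote-segment merger for multi-domain proteins,
run on the alignments. E-values follow Karlin–Altschul theory,
`E = K m n exp(-lambda S)`, with published gapped (lambda, K) for
BLOSUM62/11/1 and an exact ungapped solver as fallback. Hits are ranked
per query by E-value and truncated to `rpq`.

## Worked example

Generate a small synthetic search (a 300-residue query, its mutated copy —
20% substitutions plus two indels — among 10 random decoys), then search:

```python
from zonescan.io import write_fasta
from zonescan.synthetic import planted_homolog_trial
q, subs, _ = planted_homolog_trial(seed=7, n_decoys=10)
write_fasta([q], "query.fa"); write_fasta(subs, "db.fa")
```

```sh
zonescan query.fa db.fa --omode NCBI_M8
```

prints (12-column BLAST tabular: query, subject, % identity, alignment
length, mismatches, gap openings, query start/end, subject start/end,
E-value, bit score):

```
query0	planted	74.52	310	63	2	1	300	1	304	5e-137	472.6
query0	decoy3	31.82	22	15	0	164	185	156	177	2.08	18.9
```

The planted homolog is recovered across its full length at 74.5% identity
with two gap openings (the two planted indels) and an overwhelming E-value;
the only other reported similarity is a marginal 22-residue chance match
(E = 2.08). All parameters (`--ksize`, `--approx`, `--kthresh`,
`--mxshift`, `--rpq`, `--omode`, gap penalties, ...) are available on the
command line or in a `key value` configuration file; the command line takes
precedence. `zonescan -h` lists everything with defaults.

The same pipeline is available as a library:

```python
from zonescan import search_records, SearchParams
hits = search_records([q], subs, SearchParams(approx=0.9, kthresh=26))
```

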