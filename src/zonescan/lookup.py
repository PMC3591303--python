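"""Direct-addressed query index over diversified k-tuples.

The index maps every one of the ``20**k`` tuple codes to the list of places
in the query set where a *sufficiently similar* tuple occurs.  Sufficient
similarity of a candidate tuple t' to an occurring query tuple t means
``match_score(t', t) >= approx * self_score(t)``.  Neighborhoods are
enumerated by a depth-first walk of the 20-way, k-level tuple trie with
branch-and-bound pruning: a partial prefix is abandoned as soon as its score
plus the best possible (self-matching) suffix falls below the threshold,
which is safe because self-match scores dominate each matrix row.  The walk
is realised level-by-level on numpy arrays rather than by recursion.

Storage follows a two-pass arena scheme: pass 1 only counts entries per
code so one contiguous entry array can be allocated and partitioned exactly;
pass 2 fills the regions.  Diversification is recomputed in pass 2 instead
of cached, keeping peak memory at the size of the final table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scoring import (
    SubstitutionMatrix,
    code_digits,
    encode_sequence_tuples,
    suffix_self_scores,
)

logger = logging.getLogger(__name__)

K_MIN, K_MAX = 3, 6


def _check_k(k: int) -> None:
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")


def _check_approx(approx: float) -> None:
    if not 0.0 < approx <= 1.0:
        raise ValueError(f"approx must be in (0, 1], got {approx}")


def diversify_tuple(
    code: int, k: int, matrix: SubstitutionMatrix, approx: float
) -> tuple[np.ndarray, np.ndarray]:
    """All tuple codes scoring at least ``approx * self_score`` against ``code``.

    Returns ``(codes, suffix_scores)``: codes in increasing order, and for
    each one the k suffix match scores against the original tuple
    (element 0 = full-tuple match score).  The integer match scores are
    compared against the real-valued threshold directly, without rounding.
    """
    _check_approx(approx)
    target = code_digits(np.array([code]), k)[0].astype(np.int64)
    self_suf = suffix_self_scores(target, matrix)
    threshold = approx * float(self_suf[0])

    prefixes = np.zeros(1, dtype=np.int64)
    scores = np.zeros(1, dtype=np.int64)
    for p in range(k):
        step = matrix.scores[:, target[p]]  # score of each residue vs target[p]
        new_scores = (scores[:, None] + step[None, :]).ravel()
        new_prefixes = (prefixes[:, None] * 20 + np.arange(20, dtype=np.int64)[None, :]).ravel()
        bound = int(self_suf[p + 1]) if p + 1 < k else 0
        keep = new_scores + bound >= threshold
        prefixes, scores = new_prefixes[keep], new_scores[keep]
        if prefixes.size == 0:
            break

    if prefixes.size == 0:
        return prefixes, np.empty((0, k), dtype=np.int64)
    digits = code_digits(prefixes, k).astype(np.int64)
    per_pos = matrix.scores[digits, target[None, :]]
    sufs = per_pos[:, ::-1].cumsum(axis=1)[:, ::-1]
    return prefixes, sufs


@dataclass
class QueryCatalog:
    """Identifiers, lengths and concatenated global offsets of the queries."""

    ids: list[str]
    lengths: np.ndarray
    starts: np.ndarray  # global offset of each query in the concatenation
    encoded: list[np.ndarray]  # residue indices per query

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())


@dataclass
class LookupTable:
    k: int
    approx: float
    matrix: SubstitutionMatrix
    catalog: QueryCatalog
    offsets: np.ndarray = field(repr=False)  # region bounds per code, len 20**k + 1
    entry_query: np.ndarray = field(repr=False)
    entry_offset: np.ndarray = field(repr=False)
    entry_suffix: np.ndarray = field(repr=False)  # (N, k) suffix match scores
    exact_tuple_count: int = 0

    @property
    def total_entries(self) -> int:
        return int(self.offsets[-1])

    def lookup(self, code: int):
        """Constant-time view of the entries for a tuple code."""
        if not 0 <= code < 20**self.k:
            raise IndexError(f"tuple code {code} out of range for k={self.k}")
        lo, hi = int(self.offsets[code]), int(self.offsets[code + 1])
        return (
            self.entry_query[lo:hi],
            self.entry_offset[lo:hi],
            self.entry_suffix[lo:hi],
        )


def lookup(table: LookupTable, code: int):
    return table.lookup(code)


def build_lookup_table(
    queries,
    matrix: SubstitutionMatrix,
    k: int = 5,
    approx: float = 0.85,
    ids: list[str] | None = None,
) -> LookupTable:
    """Two-pass construction of the diversified query index.

    ``queries`` is a sequence of residue strings (or objects with ``id`` and
    ``seq`` attributes).  Queries shorter than k contribute nothing; k-tuples
    containing non-standard residues are skipped entirely.
    """
    _check_k(k)
    _check_approx(approx)
    seqs: list[str] = []
    rec_ids: list[str] = []
    for i, q in enumerate(queries):
        if hasattr(q, "seq"):
            seqs.append(str(q.seq))
            rec_ids.append(getattr(q, "id", str(i)))
        else:
            seqs.append(str(q))
            rec_ids.append(ids[i] if ids is not None else str(i))
    if not seqs:
        raise ValueError("query set is empty")
    if any(len(s) == 0 for s in seqs):
        raise ValueError("queries must be non-empty")

    encoded = [matrix.alphabet.encode(s) for s in seqs]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
    catalog = QueryCatalog(ids=rec_ids, lengths=lengths, starts=starts, encoded=encoded)

    # gather exact occurrences: (code, query, offset) for every valid window
    all_codes, all_q, all_off = [], [], []
    for qi, idx in enumerate(encoded):
        codes, valid = encode_sequence_tuples(idx, k)
        pos = np.nonzero(valid)[0]
        all_codes.append(codes[pos])
        all_q.append(np.full(pos.size, qi, dtype=np.int32))
        all_off.append(pos.astype(np.int32))
    occ_codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
    occ_q = np.concatenate(all_q) if all_q else np.empty(0, np.int32)
    occ_off = np.concatenate(all_off) if all_off else np.empty(0, np.int32)

    order = np.argsort(occ_codes, kind="stable")
    occ_codes, occ_q, occ_off = occ_codes[order], occ_q[order], occ_off[order]
    uniq_codes, group_starts, group_counts = np.unique(
        occ_codes, return_index=True, return_counts=True
    )

    n_codes = 20**k
    counts = np.zeros(n_codes, dtype=np.int64)
    # pass 1: diversify each occurring code, crediting its occurrence count
    # to every neighbor (the code itself is always its own neighbor)
    for code, cnt in zip(uniq_codes, group_counts):
        neighbors, _ = diversify_tuple(int(code), k, matrix, approx)
        counts[neighbors] += int(cnt)

    offsets = np.zeros(n_codes + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    n_total = int(offsets[-1])
    entry_query = np.empty(n_total, dtype=np.int32)
    entry_offset = np.empty(n_total, dtype=np.int32)
    entry_suffix = np.empty((n_total, k), dtype=np.int32)

    # pass 2: re-diversify and copy locations into each neighbor's region
    fill = offsets[:-1].copy()
    for code, gs, cnt in zip(uniq_codes, group_starts, group_counts):
        qs = occ_q[gs : gs + cnt]
        offs = occ_off[gs : gs + cnt]
        neighbors, sufs = diversify_tuple(int(code), k, matrix, approx)
        for nb, srow in zip(neighbors, sufs):
            dest = int(fill[nb])
            entry_query[dest : dest + cnt] = qs
            entry_offset[dest : dest + cnt] = offs
            entry_suffix[dest : dest + cnt] = srow
            fill[nb] += cnt
    if not np.array_equal(fill, offsets[1:]):
        raise AssertionError("lookup table regions not exactly filled")

    logger.info(
        "lookup table: %d queries, %d exact tuples, %d entries after diversification",
        len(seqs), occ_codes.size, n_total,
    )
    return LookupTable(
        k=k,
        approx=approx,
        matrix=matrix,
        catalog=catalog,
        offsets=offsets,
        entry_query=entry_query,
        entry_offset=entry_offset,
        entry_suffix=entry_suffix,
        exact_tuple_count=int(occ_codes.size),
    )
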