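"""Diagonal similarity-zone accumulation over streamed subject sequences.

Conceptually the search space for one subject is the similarity matrix whose
columns are positions in the concatenated query set and whose rows are
positions in the subject.  Every k-tuple seed match lands on one diagonal of
that matrix; nearby matches are aggregated into *similarity zones* —
diagonal-oriented rectangles carrying a cumulative match score.  Zones grow
along their diagonal, absorb matches on adjacent diagonals (up to ``mxshift``
away), and finally undergo single-linkage clustering so that compatible
zones separated by larger gaps are merged before alignment.

Per-diagonal state lives in flat arrays indexed by diagonal number and is
invalidated lazily: an entry is only trusted when its recorded subject
ordinal matches the subject currently being scanned, so nothing is cleared
between subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lookup import LookupTable
from .scoring import encode_sequence_tuples

logger = logging.getLogger(__name__)

SENTINEL = -1


@dataclass
class SearchParams:
    """Tunable knobs of the search pipeline.

    All scores are in the integer units of the substitution matrix.
    """

    k: int = 5
    approx: float = 0.85
    kthresh: int = 18          # zone score triggering downstream processing
    mxshift: int = 3           # lateral merge reach, in diagonals
    gip: int = 11              # gap initiation penalty (positive)
    gep: int = 1               # gap extension penalty per residue (positive)
    max_subject_len: int = 50_000
    band_extension: int = 16   # residues added around a zone before alignment
    rpq: int = 100             # results reported per query
    min_score: int = 0         # post-alignment Smith-Waterman score filter
    max_evalue: float = 10.0   # report threshold
    max_zones: int = 2_000_000
    max_hits: int = 65_536
    repeat_filter: bool = True
    merge_remote: bool = False

    def __post_init__(self) -> None:
        if self.mxshift < 0:
            raise ValueError("mxshift must be >= 0")
        if self.gip < 0 or self.gep < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.kthresh <= 0:
            raise ValueError("kthresh must be > 0")
        if not 0.0 < self.approx <= 1.0:
            raise ValueError("approx must be in (0, 1]")


def affine_gap_penalty(length: int, params: SearchParams) -> int:
    """Cost of a gap: 0 for length 0, else gip + gep * length."""
    if length < 0:
        raise ValueError("gap length must be >= 0")
    if length == 0:
        return 0
    return params.gip + params.gep * length


def diagonal_index(query_global_offset: int, subject_offset: int, params: SearchParams) -> int:
    """Index of the similarity-matrix diagonal through (query, subject).

    The index is constant along a diagonal and lies in
    ``[0, total_query_length + max_subject_len)``.
    """
    if subject_offset >= params.max_subject_len:
        raise ValueError(
            f"subject offset {subject_offset} exceeds max_subject_len={params.max_subject_len}"
        )
    return query_global_offset - subject_offset + params.max_subject_len


@dataclass
class MergedZone:
    """A completed similarity zone ready for band extension and alignment."""

    query_index: int
    diag_lo: int
    diag_hi: int
    subj_lo: int
    subj_hi: int
    score: int


def _prorated_pair_score(
    score_a: int, alo: int, ahi: int, score_b: int, blo: int, bhi: int
) -> float:
    """Sum of two zone scores with the smaller zone prorated by the subject
    overlap: an overlap of v residues scales the shorter zone's score by
    (1 - v / its_length), so fully contained zones contribute nothing new."""
    v = min(ahi, bhi) - max(alo, blo) + 1
    if v <= 0:
        return float(score_a + score_b)
    len_a, len_b = ahi - alo + 1, bhi - blo + 1
    if len_a <= len_b:
        return score_b + score_a * max(0.0, 1.0 - v / len_a)
    return score_a + score_b * max(0.0, 1.0 - v / len_b)


class ZoneScanner:
    """Streaming scanner: feed subject sequences one by one.

    Diagonal-entry arrays, the zone arena and the hits array are allocated
    once; per-subject state is reset through fill counters and lazy
    (subject-ordinal) invalidation of diagonal entries.
    """

    def __init__(self, table: LookupTable, params: SearchParams):
        self.table = table
        self.params = params
        n_diag = table.catalog.total_length + params.max_subject_len
        self._d_last = np.zeros(n_diag, dtype=np.int64)    # subject start of last match
        self._d_zone = np.full(n_diag, SENTINEL, dtype=np.int64)
        self._d_subj = np.full(n_diag, SENTINEL, dtype=np.int64)  # subject ordinal
        self._d_query = np.full(n_diag, SENTINEL, dtype=np.int64)
        self._subject_ord = -1
        cap = params.max_zones
        self._z_diag_lo = np.zeros(cap, dtype=np.int64)
        self._z_diag_hi = np.zeros(cap, dtype=np.int64)
        self._z_subj_lo = np.zeros(cap, dtype=np.int64)
        self._z_subj_hi = np.zeros(cap, dtype=np.int64)
        self._z_score = np.zeros(cap, dtype=np.int64)
        self._z_best = np.zeros(cap, dtype=np.int64)
        self._z_query = np.zeros(cap, dtype=np.int64)
        self._z_skip = np.zeros(cap, dtype=bool)
        self._z_hit = np.zeros(cap, dtype=np.int64)
        self._zone_fill = 0
        self._hits: list[int] = []
        self._zone_warned = False
        self._hits_warned = False
        self.zones_created = 0
        self.zones_merged = 0

    # -- zone arena ---------------------------------------------------------

    def _new_zone(self, diag: int, subj: int, query: int, score: int) -> int:
        if self._zone_fill >= self.params.max_zones:
            if not self._zone_warned:
                logger.warning("zone arena exhausted; further zones are dropped")
                self._zone_warned = True
            return SENTINEL
        z = self._zone_fill
        self._zone_fill += 1
        self._z_diag_lo[z] = self._z_diag_hi[z] = diag
        self._z_subj_lo[z] = subj
        self._z_subj_hi[z] = subj + self.table.k - 1
        self._z_score[z] = self._z_best[z] = score
        self._z_query[z] = query
        self._z_skip[z] = False
        self._z_hit[z] = SENTINEL
        self.zones_created += 1
        return z

    def _record_hit(self, z: int) -> None:
        """List a zone in the hits array the first time its running score
        reaches kthresh; the sentinel hit index guards against duplicates."""
        if z == SENTINEL or self._z_hit[z] != SENTINEL:
            return
        if self._z_score[z] < self.params.kthresh:
            return
        if len(self._hits) >= self.params.max_hits:
            if not self._hits_warned:
                logger.warning("hits array exhausted; hit recording stopped")
                self._hits_warned = True
            return
        self._z_hit[z] = len(self._hits)
        self._hits.append(z)

    def _merge_adjacent(self, z: int, diag: int, query: int) -> int:
        """Try to merge the just-updated zone with zones on diagonals up to
        mxshift away (both directions).  Returns the surviving zone index."""
        p = self.params
        ord_ = self._subject_ord
        n_diag = self._d_zone.shape[0]
        for delta in range(1, p.mxshift + 1):
            for nd in (diag - delta, diag + delta):
                if not 0 <= nd < n_diag:
                    continue
                if self._d_subj[nd] != ord_ or self._d_query[nd] != query:
                    continue
                z2 = int(self._d_zone[nd])
                if z2 == SENTINEL or z2 == z or self._z_skip[z2]:
                    continue
                gap_diag = max(
                    int(self._z_diag_lo[z] - self._z_diag_hi[z2]),
                    int(self._z_diag_lo[z2] - self._z_diag_hi[z]),
                    0,
                )
                est = _prorated_pair_score(
                    int(self._z_score[z]),
                    int(self._z_subj_lo[z]), int(self._z_subj_hi[z]),
                    int(self._z_score[z2]),
                    int(self._z_subj_lo[z2]), int(self._z_subj_hi[z2]),
                ) - affine_gap_penalty(gap_diag, p)
                if est <= 0:
                    continue
                surv, lose = (z, z2) if z < z2 else (z2, z)
                self._z_diag_lo[surv] = min(self._z_diag_lo[z], self._z_diag_lo[z2])
                self._z_diag_hi[surv] = max(self._z_diag_hi[z], self._z_diag_hi[z2])
                self._z_subj_lo[surv] = min(self._z_subj_lo[z], self._z_subj_lo[z2])
                self._z_subj_hi[surv] = max(self._z_subj_hi[z], self._z_subj_hi[z2])
                new_score = int(est)
                self._z_score[surv] = new_score
                self._z_best[surv] = max(
                    int(self._z_best[z]), int(self._z_best[z2]), new_score
                )
                self._z_skip[lose] = True
                # re-point every diagonal entry of the losing zone
                lo = max(0, int(self._z_diag_lo[lose]))
                hi = min(n_diag - 1, int(self._z_diag_hi[lose]))
                span = slice(lo, hi + 1)
                mask = (
                    (self._d_zone[span] == lose)
                    & (self._d_subj[span] == ord_)
                    & (self._d_query[span] == query)
                )
                self._d_zone[span][mask] = surv
                self._d_zone[nd] = surv
                self._d_zone[diag] = surv
                # keep merged zones visible in the hits array
                if self._z_hit[lose] != SENTINEL and self._z_hit[surv] == SENTINEL:
                    slot = int(self._z_hit[lose])
                    self._hits[slot] = surv
                    self._z_hit[surv] = slot
                    self._z_hit[lose] = SENTINEL
                self.zones_merged += 1
                z = surv
        return z

    def _process_match(
        self, query: int, q_glob: int, s_off: int, suffix_scores: np.ndarray
    ) -> None:
        p = self.params
        k = self.table.k
        diag = q_glob - s_off + p.max_subject_len
        ord_ = self._subject_ord
        fresh = self._d_subj[diag] != ord_ or self._d_query[diag] != query
        if not fresh:
            z = int(self._d_zone[diag])
            fresh = z == SENTINEL
        if fresh:
            # cases 1-3: unused / stale subject / different query
            z = self._new_zone(diag, s_off, query, int(suffix_scores[0]))
        else:
            # case 4: extend the active zone on this diagonal
            d = s_off - int(self._d_last[diag])
            if d <= 0:
                return  # duplicate or out-of-order entry on this diagonal
            overlap = k - d if d < k else 0
            incremental = int(suffix_scores[overlap])
            gap = affine_gap_penalty(d - k, p) if d > k else 0
            extended = int(self._z_score[z]) + incremental - gap
            if extended > 0:
                self._z_score[z] = extended
                if extended > self._z_best[z]:
                    self._z_best[z] = extended
                self._z_subj_hi[z] = max(int(self._z_subj_hi[z]), s_off + k - 1)
                self._z_diag_lo[z] = min(int(self._z_diag_lo[z]), diag)
                self._z_diag_hi[z] = max(int(self._z_diag_hi[z]), diag)
            else:
                # previous zone stays active (it may already be in hits);
                # the diagonal is handed to a fresh zone
                z = self._new_zone(diag, s_off, query, int(suffix_scores[0]))
        self._d_last[diag] = s_off
        self._d_subj[diag] = ord_
        self._d_query[diag] = query
        self._d_zone[diag] = z
        if z == SENTINEL:
            return
        z = self._merge_adjacent(z, diag, query)
        self._record_hit(z)

    # -- clustering ---------------------------------------------------------

    def _cluster_hits(self) -> list[MergedZone]:
        p = self.params
        valid = [z for z in self._hits if not self._z_skip[z]]
        if not valid:
            return []
        parent = {z: z for z in valid}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(valid):
            for b in valid[i + 1 :]:
                if self._z_query[a] != self._z_query[b]:
                    continue
                gap_diag = max(
                    int(self._z_diag_lo[a] - self._z_diag_hi[b]),
                    int(self._z_diag_lo[b] - self._z_diag_hi[a]),
                    0,
                )
                combined = _prorated_pair_score(
                    int(self._z_best[a]),
                    int(self._z_subj_lo[a]), int(self._z_subj_hi[a]),
                    int(self._z_best[b]),
                    int(self._z_subj_lo[b]), int(self._z_subj_hi[b]),
                )
                if combined > affine_gap_penalty(gap_diag, p):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)

        components: dict[int, list[int]] = {}
        for z in valid:
            components.setdefault(find(z), []).append(z)

        out: list[MergedZone] = []
        for root in sorted(components):
            members = sorted(components[root])
            first = members[0]
            diag_lo = min(int(self._z_diag_lo[m]) for m in members)
            diag_hi = max(int(self._z_diag_hi[m]) for m in members)
            subj_lo = min(int(self._z_subj_lo[m]) for m in members)
            subj_hi = max(int(self._z_subj_hi[m]) for m in members)
            # chain score: members in subject order, overlap-prorated, minus
            # the diagonal gap penalty between consecutive members
            ordered = sorted(members, key=lambda m: int(self._z_subj_lo[m]))
            score = float(self._z_best[ordered[0]])
            cur_lo = int(self._z_subj_lo[ordered[0]])
            cur_hi = int(self._z_subj_hi[ordered[0]])
            for m in ordered[1:]:
                gap_diag = max(
                    int(self._z_diag_lo[first] - self._z_diag_hi[m]),
                    int(self._z_diag_lo[m] - self._z_diag_hi[first]),
                    0,
                )
                score = _prorated_pair_score(
                    int(round(score)), cur_lo, cur_hi,
                    int(self._z_best[m]),
                    int(self._z_subj_lo[m]), int(self._z_subj_hi[m]),
                ) - affine_gap_penalty(gap_diag, p)
                cur_lo = min(cur_lo, int(self._z_subj_lo[m]))
                cur_hi = max(cur_hi, int(self._z_subj_hi[m]))
            best = max(max(int(self._z_best[m]) for m in members), int(round(score)))
            for m in members[1:]:
                self._z_skip[m] = True
            out.append(
                MergedZone(
                    query_index=int(self._z_query[first]),
                    diag_lo=diag_lo,
                    diag_hi=diag_hi,
                    subj_lo=subj_lo,
                    subj_hi=subj_hi,
                    score=best,
                )
            )
        return out

    # -- public entry point -------------------------------------------------

    def scan(self, subject) -> list[MergedZone]:
        """Scan one subject sequence; returns merged zones grouped by the
        ``query_index`` they belong to (ordering: arena order)."""
        p = self.params
        table = self.table
        if hasattr(subject, "seq"):
            subject = str(subject.seq)
        if isinstance(subject, str):
            s_idx = table.matrix.alphabet.encode(subject)
        else:
            s_idx = np.asarray(subject)
        if len(s_idx) > p.max_subject_len:
            raise ValueError(
                f"subject of length {len(s_idx)} exceeds max_subject_len={p.max_subject_len}"
            )
        self._subject_ord += 1
        self._zone_fill = 0
        self._hits = []
        starts = table.catalog.starts
        codes, valid_mask = encode_sequence_tuples(s_idx, table.k)
        offsets = table.offsets
        for s_off in np.nonzero(valid_mask)[0]:
            code = int(codes[s_off])
            lo, hi = int(offsets[code]), int(offsets[code + 1])
            if lo == hi:
                continue
            eq = table.entry_query[lo:hi]
            eo = table.entry_offset[lo:hi]
            es = table.entry_suffix[lo:hi]
            s_off_i = int(s_off)
            for j in range(hi - lo):
                q = int(eq[j])
                self._process_match(q, int(starts[q]) + int(eo[j]), s_off_i, es[j])
        return self._cluster_hits()


def scan_subject(subject, table: LookupTable, params: SearchParams) -> list[MergedZone]:
    """One-shot scan of a single subject with freshly allocated state."""
    return ZoneScanner(table, params).scan(subject)
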