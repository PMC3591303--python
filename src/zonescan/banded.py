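"""Banded local alignment with affine gaps.

A merged similarity zone is widened into an :class:`AlignmentBand` and a
local (Smith-Waterman scored) alignment is computed by dynamic programming
restricted to the cells inside the band.  Memory and time are proportional
to ``band_width * band_length`` rather than the full ``m * n`` rectangle.
The recurrence is the usual three-state affine one (match state plus one
gap state per sequence); a gap of length L costs ``gip + gep * L``, the
first gapped residue paying ``gip + gep``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .scoring import SubstitutionMatrix
from .zones import MergedZone, SearchParams

NEG = -(10**15)


@dataclass
class AlignmentBand:
    """Diagonal band in local (query, subject) coordinates, inclusive.

    ``d_lo..d_hi`` bound the diagonals ``q - s`` admitted to the DP.
    """

    query_index: int
    q_lo: int
    q_hi: int
    s_lo: int
    s_hi: int
    d_lo: int
    d_hi: int

    def contains(self, q: int, s: int) -> bool:
        return (
            self.q_lo <= q <= self.q_hi
            and self.s_lo <= s <= self.s_hi
            and self.d_lo <= q - s <= self.d_hi
        )


@dataclass
class Alignment:
    """A banded-DP local alignment.  Coordinates are 0-based half-open.

    Path ops: ``M`` aligned column (match or mismatch), ``I`` query residue
    against a gap (gap in subject), ``D`` subject residue against a gap
    (gap in query).
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    sw_score: int
    path: list[tuple[str, int]]
    identities: int
    mismatches: int
    gap_openings: int
    aligned_length: int
    evalue: float | None = None
    bit_score: float | None = None
    query_index: int = 0

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identities / self.aligned_length if self.aligned_length else 0.0


def extend_band(
    zone: MergedZone,
    params: SearchParams,
    query_len: int,
    subject_len: int,
    query_global_start: int,
) -> AlignmentBand:
    """Widen a zone's rectangle by ``band_extension``: half the extension on
    each side of the diagonal span, the full extension along the diagonal in
    both directions, clipped to the sequence ends."""
    be = params.band_extension
    half = (be + 1) // 2
    d_lo = zone.diag_lo - params.max_subject_len - query_global_start - half
    d_hi = zone.diag_hi - params.max_subject_len - query_global_start + half
    s_lo = zone.subj_lo - be
    s_hi = zone.subj_hi + be
    q_lo = max(0, s_lo + d_lo)
    q_hi = min(query_len - 1, s_hi + d_hi)
    s_lo = max(0, s_lo)
    s_hi = min(subject_len - 1, s_hi)
    return AlignmentBand(
        query_index=zone.query_index,
        q_lo=q_lo, q_hi=q_hi, s_lo=s_lo, s_hi=s_hi, d_lo=d_lo, d_hi=d_hi,
    )


def full_band(query_len: int, subject_len: int, query_index: int = 0) -> AlignmentBand:
    """Band covering the entire DP rectangle (no restriction)."""
    return AlignmentBand(
        query_index=query_index,
        q_lo=0, q_hi=query_len - 1, s_lo=0, s_hi=subject_len - 1,
        d_lo=-(subject_len - 1), d_hi=query_len - 1,
    )


# traceback codes for the H state
_TB_NONE, _TB_DIAG, _TB_E, _TB_F, _TB_START = 0, 1, 2, 3, 4


def banded_align(
    query,
    subject,
    band: AlignmentBand,
    matrix: SubstitutionMatrix,
    params: SearchParams,
    query_id: str = "query",
    subject_id: str = "subject",
) -> Alignment | None:
    """Best local alignment restricted to the band, or None if no cell
    scores above zero.

    Deterministic tie-breaking: the earliest best end cell in (subject,
    query) scan order wins, and the traceback prefers diagonal moves over
    gaps in the query over gaps in the subject.
    """
    alphabet = matrix.alphabet
    q_idx = alphabet.encode(query) if isinstance(query, str) else query
    s_idx = alphabet.encode(subject) if isinstance(subject, str) else subject
    if band.q_lo > band.q_hi or band.s_lo > band.s_hi or band.d_lo > band.d_hi:
        return None
    if band.q_hi >= len(q_idx) or band.s_hi >= len(s_idx):
        raise ValueError("band exceeds sequence bounds")

    gop = params.gip + params.gep  # first gapped residue
    gext = params.gep
    W = band.d_hi - band.d_lo + 1
    n_rows = band.s_hi - band.s_lo + 1

    # cell (row i: s = s_lo + i, column c: q = s + d_lo + c)
    prev_h = [NEG] * W
    prev_f = [NEG] * W
    tb_h: list[list[int]] = []
    tb_e: list[list[int]] = []  # 0 opened from H, 1 extended
    tb_f: list[list[int]] = []
    best_score = 0
    best_rc: tuple[int, int] | None = None
    pair = matrix.pair_score

    for i in range(n_rows):
        s = band.s_lo + i
        base = s + band.d_lo  # q at column 0
        c_lo = max(0, band.q_lo - base)
        c_hi = min(W - 1, band.q_hi - base)
        row_h = [NEG] * W
        row_f = [NEG] * W
        row_tb_h = [_TB_NONE] * W
        row_tb_e = [0] * W
        row_tb_f = [0] * W
        e = NEG
        s_res = int(s_idx[s])
        for c in range(c_lo, c_hi + 1):
            q = base + c
            # E: gap in subject, predecessor (s, q-1) = same row, c-1
            h_left = row_h[c - 1] if c > 0 else NEG
            open_e = h_left - gop if h_left != NEG else NEG
            ext_e = e - gext if e != NEG else NEG
            if open_e >= ext_e:
                e, te = open_e, 0
            else:
                e, te = ext_e, 1
            # F: gap in query, predecessor (s-1, q) = previous row, c+1
            h_up = prev_h[c + 1] if c + 1 < W else NEG
            f_up = prev_f[c + 1] if c + 1 < W else NEG
            open_f = h_up - gop if h_up != NEG else NEG
            ext_f = f_up - gext if f_up != NEG else NEG
            if open_f >= ext_f:
                f, tf = open_f, 0
            else:
                f, tf = ext_f, 1
            # H: fresh start vs diagonal continuation vs gap states
            sc = pair(int(q_idx[q]), s_res)
            pred = prev_h[c]
            if pred != NEG and pred > 0:
                h, th = pred + sc, _TB_DIAG
            else:
                h, th = sc, _TB_START
            if f > h:
                h, th = f, _TB_F
            if e > h:
                h, th = e, _TB_E
            if h < 0:
                h, th = NEG, _TB_NONE  # never worth keeping a negative local prefix
            row_h[c] = h
            row_f[c] = f
            row_tb_h[c] = th
            row_tb_e[c] = te
            row_tb_f[c] = tf
            if h != NEG and h > best_score:
                best_score = h
                best_rc = (i, c)
        prev_h, prev_f = row_h, row_f
        tb_h.append(row_tb_h)
        tb_e.append(row_tb_e)
        tb_f.append(row_tb_f)

    if best_rc is None or best_score <= 0:
        return None

    # traceback from the best cell
    i, c = best_rc
    end_s = band.s_lo + i
    end_q = end_s + band.d_lo + c
    ops_rev: list[str] = []
    state = "H"
    while True:
        if state == "H":
            th = tb_h[i][c]
            if th == _TB_START:
                ops_rev.append("M")
                break
            if th == _TB_DIAG:
                ops_rev.append("M")
                i -= 1
                continue
            state = "E" if th == _TB_E else "F"
            continue
        if state == "E":
            ops_rev.append("I")
            te = tb_e[i][c]
            c -= 1
            state = "H" if te == 0 else "E"
            continue
        ops_rev.append("D")
        tf = tb_f[i][c]
        i -= 1
        c += 1
        state = "H" if tf == 0 else "F"

    ops = ops_rev[::-1]
    n_m = ops.count("M")
    n_i = ops.count("I")
    n_d = ops.count("D")
    q_start = end_q + 1 - (n_m + n_i)
    s_start = end_s + 1 - (n_m + n_d)

    identities = mismatches = gap_openings = 0
    qp, sp = q_start, s_start
    prev_op = None
    for op in ops:
        if op == "M":
            if int(q_idx[qp]) == int(s_idx[sp]) and int(q_idx[qp]) != 255:
                identities += 1
            else:
                mismatches += 1
            qp += 1
            sp += 1
        elif op == "I":
            if prev_op != "I":
                gap_openings += 1
            qp += 1
        else:
            if prev_op != "D":
                gap_openings += 1
            sp += 1
        prev_op = op
    path = [(op, sum(1 for _ in grp)) for op, grp in groupby(ops)]

    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q_start,
        q_end=end_q + 1,
        s_start=s_start,
        s_end=end_s + 1,
        sw_score=int(best_score),
        path=path,
        identities=identities,
        mismatches=mismatches,
        gap_openings=gap_openings,
        aligned_length=len(ops),
        query_index=band.query_index,
    )
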