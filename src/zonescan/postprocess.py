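"""Result post-processing: score/repeat filters, remote-segment chaining,
Karlin-Altschul statistics and ranking.

E-values follow the classic theory for local alignment scores: the expected
number of distinct alignments scoring at least S in an m x n search space is
``E = K * m * n * exp(-lambda * S)``.  For gapped alignments lambda and K
cannot be derived analytically; a small table of published, empirically fit
parameters per (matrix, gap open, gap extend) combination is bundled, and
for combinations absent from it the exact *ungapped* parameters are solved
from the matrix and background residue frequencies (a conservative
fallback: ungapped lambda is larger, so E-values come out smaller).
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .banded import Alignment
from .zones import SearchParams, affine_gap_penalty
from .scoring import SubstitutionMatrix

logger = logging.getLogger(__name__)

#: Robinson & Robinson amino-acid background frequencies, in the NCBI
#: matrix residue order ARNDCQEGHILKMFPSTWYV.
ROBINSON_FREQUENCIES = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


class StatisticsError(ValueError):
    """Matrix/frequency combination unsuitable for Karlin-Altschul theory."""


@dataclass
class KarlinParams:
    lam: float  # nats per score unit
    K: float
    frequencies: np.ndarray = field(repr=False)
    regime: str = "ungapped"  # or "gapped-precomputed"

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise StatisticsError("lambda and K must be positive")
        if not math.isclose(float(np.sum(self.frequencies)), 1.0, abs_tol=1e-6):
            raise StatisticsError("background frequencies must sum to 1")


def uniform_frequencies() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def robinson_frequencies(matrix: SubstitutionMatrix) -> np.ndarray:
    p = np.array([ROBINSON_FREQUENCIES[c] for c in matrix.alphabet.symbols])
    return p / p.sum()


def solve_ungapped_lambda(matrix: SubstitutionMatrix, frequencies=None) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda s_ij) = 1.

    Requires a negative expected score and at least one positive score
    (otherwise no positive root exists and the statistics are undefined).
    """
    p = uniform_frequencies() if frequencies is None else np.asarray(frequencies, float)
    p = p / p.sum()
    s = matrix.scores.astype(float)
    pij = np.outer(p, p)
    expected = float((pij * s).sum())
    if expected >= 0:
        raise StatisticsError(f"expected score {expected:.4f} is not negative")
    if s.max() <= 0:
        raise StatisticsError("matrix has no positive score")

    def f(lam: float) -> float:
        return float((pij * np.exp(lam * s)).sum()) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 100:
            raise StatisticsError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-14, rtol=1e-15))
    if abs(f(lam)) >= 1e-9:
        raise StatisticsError(f"lambda residual {f(lam):.3e} above tolerance")
    return lam


def solve_ungapped_K(matrix: SubstitutionMatrix, lam: float, frequencies=None) -> float:
    """Crude K estimate for the ungapped fallback regime.

    Uses the high-score approximation K ~ (lambda * |E[s]|) / (max pair
    score * e); adequate for ranking, not for cross-tool E-value parity.
    """
    p = uniform_frequencies() if frequencies is None else np.asarray(frequencies, float)
    p = p / p.sum()
    s = matrix.scores.astype(float)
    expected = abs(float((np.outer(p, p) * s).sum()))
    return max(1e-4, lam * expected / (float(s.max()) * math.e))


def _load_gapped_table() -> dict[tuple[str, int, int], tuple[float, float]]:
    ref = importlib.resources.files("zonescan.data") / "gapped_params.tsv"
    out: dict[tuple[str, int, int], tuple[float, float]] = {}
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, gip, gep, lam, k = line.split("\t")
        out[(name.upper(), int(gip), int(gep))] = (float(lam), float(k))
    return out


def get_karlin_params(
    matrix: SubstitutionMatrix,
    gip: int,
    gep: int,
    frequencies=None,
) -> KarlinParams:
    """Gapped parameters from the bundled table when available, otherwise
    the exact ungapped solution (with a logged warning)."""
    p = uniform_frequencies() if frequencies is None else np.asarray(frequencies, float)
    p = p / p.sum()
    table = _load_gapped_table()
    key = (matrix.name.upper(), int(gip), int(gep))
    if key in table:
        lam, k = table[key]
        return KarlinParams(lam=lam, K=k, frequencies=p, regime="gapped-precomputed")
    logger.warning(
        "no published gapped parameters for (%s, %d, %d); "
        "falling back to ungapped statistics", matrix.name, gip, gep,
    )
    lam = solve_ungapped_lambda(matrix, p)
    k = solve_ungapped_K(matrix, lam, p)
    return KarlinParams(lam=lam, K=k, frequencies=p, regime="ungapped")


def evalue(score: float, m_len: int, n_len: int, kp: KarlinParams) -> float:
    """Expected number of chance alignments scoring >= score."""
    return kp.K * m_len * n_len * math.exp(-kp.lam * score)


def bit_score(score: float, kp: KarlinParams) -> float:
    return (kp.lam * score - math.log(kp.K)) / math.log(2.0)


def attach_statistics(alignments, query_lengths, n_len: int, kp: KarlinParams) -> None:
    """Fill evalue/bit_score in place; m_len is the length of the alignment's
    own query, n_len the total residue count of the subject database."""
    for a in alignments:
        m_len = query_lengths[a.query_index]
        a.evalue = evalue(a.sw_score, m_len, n_len, kp)
        a.bit_score = bit_score(a.sw_score, kp)


# ---------------------------------------------------------------------------
# filters


def filter_by_score(alignments: list[Alignment], min_score: int) -> list[Alignment]:
    """Keep alignments whose Smith-Waterman score reaches the threshold."""
    return [a for a in alignments if a.sw_score >= min_score]


def _overlap(lo1: int, hi1: int, lo2: int, hi2: int) -> int:
    return max(0, min(hi1, hi2) - max(lo1, lo2))


def _repeat_conflict(a: Alignment, b: Alignment, min_frac: float = 0.5) -> bool:
    q_ov = _overlap(a.q_start, a.q_end, b.q_start, b.q_end)
    s_ov = _overlap(a.s_start, a.s_end, b.s_start, b.s_end)
    q_short = min(a.q_end - a.q_start, b.q_end - b.q_start)
    s_short = min(a.s_end - a.s_start, b.s_end - b.s_start)
    same_q_diff_s = q_ov >= min_frac * q_short and s_ov == 0
    same_s_diff_q = s_ov >= min_frac * s_short and q_ov == 0
    return same_q_diff_s or same_s_diff_q


def filter_long_repeats(alignments: list[Alignment]) -> list[Alignment]:
    """Drop repeat-induced redundant similarities for one query/subject pair.

    Two alignments conflict when their intervals on one sequence overlap by
    at least half of the shorter interval while the intervals on the other
    sequence are disjoint — the signature of a repeated segment.  Conflict
    groups are closed transitively; only the best-scoring member of each
    group survives (ties: first in input order).
    """
    n = len(alignments)
    if n <= 1:
        return list(alignments)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _repeat_conflict(alignments[i], alignments[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    best: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        if r not in best or alignments[i].sw_score > alignments[best[r]].sw_score:
            best[r] = i
    keep = sorted(best.values())
    return [alignments[i] for i in keep]


# ---------------------------------------------------------------------------
# remote segment chaining


@dataclass
class SuperAlignment:
    """A chain of collinear alignment segments reported as one similarity."""

    members: list[Alignment]
    score: float
    evalue: float | None = None
    bit_score: float | None = None

    @property
    def query_id(self) -> str:
        return self.members[0].query_id

    @property
    def subject_id(self) -> str:
        return self.members[0].subject_id

    @property
    def query_index(self) -> int:
        return self.members[0].query_index

    @property
    def q_start(self) -> int:
        return self.members[0].q_start

    @property
    def q_end(self) -> int:
        return self.members[-1].q_end

    @property
    def s_start(self) -> int:
        return self.members[0].s_start

    @property
    def s_end(self) -> int:
        return self.members[-1].s_end

    @property
    def sw_score(self) -> float:
        return self.score


def merge_remote_segments(
    alignments: list[Alignment], params: SearchParams
) -> list[SuperAlignment]:
    """Chain collinear segments of one query/subject pair into
    super-alignments by dynamic programming.

    Segment j may follow segment i only when both its query and subject
    intervals start at or after i's ends; the bridge between them costs
    ``affine_gap_penalty(max(q_gap, s_gap))``.  A link is taken only when it
    improves on leaving the downstream segment alone, so singleton chains
    are always allowed and the output chains partition the input.
    """
    if not alignments:
        return []
    segs = sorted(alignments, key=lambda a: (a.q_start, a.s_start))
    n = len(segs)
    best = [float(s.sw_score) for s in segs]
    parent = [-1] * n
    for j in range(n):
        for i in range(j):
            if segs[i].q_end <= segs[j].q_start and segs[i].s_end <= segs[j].s_start:
                q_gap = segs[j].q_start - segs[i].q_end
                s_gap = segs[j].s_start - segs[i].s_end
                bridge = affine_gap_penalty(max(q_gap, s_gap), params)
                cand = best[i] + segs[j].sw_score - bridge
                if cand > best[j]:
                    best[j] = cand
                    parent[j] = i
    used = [False] * n
    out: list[SuperAlignment] = []
    for j in sorted(range(n), key=lambda j: -best[j]):
        if used[j]:
            continue
        chain = []
        node = j
        while node != -1 and not used[node]:
            chain.append(node)
            used[node] = True
            node = parent[node]
        chain.reverse()
        score = float(segs[chain[0]].sw_score)
        for a, b in zip(chain, chain[1:]):
            q_gap = segs[b].q_start - segs[a].q_end
            s_gap = segs[b].s_start - segs[a].s_end
            score += segs[b].sw_score - affine_gap_penalty(max(q_gap, s_gap), params)
        out.append(SuperAlignment(members=[segs[i] for i in chain], score=score))
    out.sort(key=lambda sa: (sa.q_start, sa.s_start))
    return out


def attach_super_statistics(supers, query_lengths, n_len: int, kp: KarlinParams) -> None:
    for sa in supers:
        m_len = query_lengths[sa.query_index]
        sa.evalue = evalue(sa.score, m_len, n_len, kp)
        sa.bit_score = bit_score(sa.score, kp)


# ---------------------------------------------------------------------------
# ranking


def rank_and_report(hits, params: SearchParams):
    """Per query: sort by ascending E-value (ties: descending score, then
    subject id), truncate to rpq, and drop hits above the E-value cutoff."""
    by_query: dict[str, list] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for qid in sorted(by_query):
        ranked = sorted(
            by_query[qid],
            key=lambda h: (h.evalue, -h.sw_score, h.subject_id),
        )
        ranked = [h for h in ranked if h.evalue is None or h.evalue <= params.max_evalue]
        out.extend(ranked[: params.rpq])
    return out
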