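"""Karlin-Altschul statistics, filters, chaining and ranking."""

import math

import numpy as np
import pytest

from zonescan.banded import Alignment
from zonescan.postprocess import (
    KarlinParams,
    StatisticsError,
    evalue,
    bit_score,
    filter_by_score,
    filter_long_repeats,
    get_karlin_params,
    merge_remote_segments,
    rank_and_report,
    robinson_frequencies,
    solve_ungapped_lambda,
    uniform_frequencies,
)
from zonescan.scoring import ResidueAlphabet, SubstitutionMatrix
from zonescan.zones import SearchParams


def _aln(qid="q", sid="s", q=(0, 100), s=(0, 100), score=100, qidx=0, ev=None):
    ln = max(q[1] - q[0], s[1] - s[0])
    return Alignment(
        query_id=qid, subject_id=sid,
        q_start=q[0], q_end=q[1], s_start=s[0], s_end=s[1],
        sw_score=score, path=[("M", ln)],
        identities=ln, mismatches=0, gap_openings=0, aligned_length=ln,
        evalue=ev, query_index=qidx,
    )


class TestLambdaSolver:
    def test_residual_below_tolerance_blosum62(self, blosum62):
        for freqs in (uniform_frequencies(), robinson_frequencies(blosum62)):
            lam = solve_ungapped_lambda(blosum62, freqs)
            p = freqs / freqs.sum()
            resid = (np.outer(p, p) * np.exp(lam * blosum62.scores)).sum() - 1.0
            assert abs(resid) < 1e-9
            assert lam > 0

    def test_two_letter_toy_matches_independent_bisection(self):
        """+1 self / -1 cross with uniform p has a closed-form check; solve
        it here by plain interval bisection, independent of the package."""
        scores = np.full((20, 20), -1, dtype=np.int64)
        np.fill_diagonal(scores, 1)
        m = SubstitutionMatrix(
            name="TOY", scores=scores, alphabet=ResidueAlphabet("ARNDCQEGHILKMFPSTWYV")
        )
        p = 1.0 / 20.0

        def f(lam):
            return 20 * p * p * math.exp(lam) + 380 * p * p * math.exp(-lam) - 1.0

        lo, hi = 1e-9, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert solve_ungapped_lambda(m) == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_all_positive_matrix_rejected(self):
        scores = np.full((20, 20), 1, dtype=np.int64)
        np.fill_diagonal(scores, 2)
        m = SubstitutionMatrix(
            name="POS", scores=scores, alphabet=ResidueAlphabet("ARNDCQEGHILKMFPSTWYV")
        )
        with pytest.raises(StatisticsError, match="not negative"):
            solve_ungapped_lambda(m)


class TestEvalue:
    KP = KarlinParams(lam=0.267, K=0.041, frequencies=uniform_frequencies(),
                      regime="gapped-precomputed")

    def test_closed_form(self):
        # independent evaluation of E = K m n exp(-lambda S)
        expected = 0.041 * 300 * 300 * math.exp(-0.267 * 100)
        assert evalue(100, 300, 300, self.KP) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_search_space(self):
        e1 = evalue(80, 250, 1000, self.KP)
        assert evalue(80, 250, 2000, self.KP) == pytest.approx(2 * e1, rel=1e-12)
        assert evalue(80, 500, 1000, self.KP) == pytest.approx(2 * e1, rel=1e-12)

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 300, 10000, self.KP) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_bit_score_formula(self):
        expected = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert bit_score(100, self.KP) == pytest.approx(expected, rel=1e-12)

    def test_gapped_table_used_for_blosum62_default(self, blosum62):
        kp = get_karlin_params(blosum62, 11, 1)
        assert kp.regime == "gapped-precomputed"
        assert kp.lam == 0.267 and kp.K == 0.041

    def test_fallback_to_ungapped_solver(self, blosum62, caplog):
        kp = get_karlin_params(blosum62, 13, 2)
        assert kp.regime == "ungapped"
        assert kp.lam == pytest.approx(solve_ungapped_lambda(blosum62), abs=1e-12)


class TestScoreFilter:
    def test_zero_threshold_identity(self):
        alns = [_aln(score=s) for s in (5, 50, 500)]
        assert filter_by_score(alns, 0) == alns

    def test_all_below_threshold_empty(self):
        assert filter_by_score([_aln(score=10)], 11) == []

    def test_exact_survivor_set(self):
        alns = [_aln(sid=f"s{i}", score=s) for i, s in enumerate([30, 70, 55, 90])]
        kept = filter_by_score(alns, 60)
        assert [a.sw_score for a in kept] == [70, 90]


class TestRepeatFilter:
    def test_single_alignment_unchanged(self):
        alns = [_aln()]
        assert filter_long_repeats(alns) == alns

    def test_repeat_collapsed_to_best(self):
        # one query domain hitting three disjoint subject copies
        alns = [
            _aln(q=(0, 40), s=(0, 40), score=180),
            _aln(q=(1, 40), s=(50, 90), score=200),
            _aln(q=(0, 39), s=(100, 140), score=170),
        ]
        kept = filter_long_repeats(alns)
        assert len(kept) == 1
        assert kept[0].sw_score == 200

    def test_fusion_domains_both_kept(self):
        # disjoint in both sequences: a genuine two-domain similarity
        alns = [
            _aln(q=(0, 40), s=(0, 40), score=180),
            _aln(q=(60, 100), s=(60, 100), score=150),
        ]
        assert len(filter_long_repeats(alns)) == 2

    def test_symmetric_case_subject_repeat(self):
        alns = [
            _aln(q=(0, 40), s=(0, 40), score=100),
            _aln(q=(60, 100), s=(0, 40), score=120),
        ]
        kept = filter_long_repeats(alns)
        assert len(kept) == 1 and kept[0].sw_score == 120


class TestRemoteMerger:
    P = SearchParams(gip=11, gep=1)

    def test_single_segment_singleton(self):
        out = merge_remote_segments([_aln()], self.P)
        assert len(out) == 1 and out[0].score == 100

    def test_two_collinear_segments_merge_when_beneficial(self):
        # gaps 30/40 residues: bridge penalty 11 + 40 = 51; 80+90-51=119 > 90
        a = _aln(q=(0, 50), s=(0, 50), score=80)
        b = _aln(q=(80, 130), s=(90, 140), score=90)
        out = merge_remote_segments([a, b], self.P)
        assert len(out) == 1
        assert out[0].score == pytest.approx(119)
        assert [m.sw_score for m in out[0].members] == [80, 90]
        assert out[0].q_start == 0 and out[0].q_end == 130

    def test_unprofitable_merge_left_separate(self):
        a = _aln(q=(0, 50), s=(0, 50), score=20)
        b = _aln(q=(80, 130), s=(500, 550), score=90)  # bridge 11+450 >> 20
        out = merge_remote_segments([a, b], self.P)
        assert len(out) == 2
        assert sorted(sa.score for sa in out) == [20, 90]

    def test_crossing_segments_never_chain(self):
        a = _aln(q=(0, 50), s=(100, 150), score=80)
        b = _aln(q=(80, 130), s=(0, 50), score=90)  # subject order reversed
        out = merge_remote_segments([a, b], self.P)
        assert len(out) == 2

    def test_chains_partition_segments(self):
        segs = [
            _aln(q=(i * 60, i * 60 + 40), s=(i * 60, i * 60 + 40), score=50)
            for i in range(4)
        ]
        out = merge_remote_segments(segs, self.P)
        assert sum(len(sa.members) for sa in out) == 4


class TestRanking:
    def test_rpq_one_keeps_best_per_query(self):
        p = SearchParams(rpq=1)
        hits = [
            _aln(qid="q1", sid="a", score=50, ev=1e-5),
            _aln(qid="q1", sid="b", score=90, ev=1e-9),
            _aln(qid="q2", sid="c", score=40, ev=1e-3),
        ]
        out = rank_and_report(hits, p)
        assert [(h.query_id, h.subject_id) for h in out] == [("q1", "b"), ("q2", "c")]

    def test_rpq_larger_than_hits_keeps_all(self):
        p = SearchParams(rpq=100)
        hits = [_aln(sid=f"s{i}", ev=10.0 ** -i) for i in range(1, 5)]
        assert len(rank_and_report(hits, p)) == 4

    def test_tie_broken_by_score_then_subject(self):
        p = SearchParams(rpq=10)
        hits = [
            _aln(sid="zzz", score=80, ev=1e-4),
            _aln(sid="aaa", score=80, ev=1e-4),
            _aln(sid="mmm", score=95, ev=1e-4),
        ]
        out = rank_and_report(hits, p)
        assert [h.subject_id for h in out] == ["mmm", "aaa", "zzz"]

    def test_evalue_cutoff_applied(self):
        p = SearchParams(rpq=10, max_evalue=1.0)
        hits = [_aln(sid="keep", ev=0.5), _aln(sid="drop", ev=5.0)]
        assert [h.subject_id for h in rank_and_report(hits, p)] == ["keep"]
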