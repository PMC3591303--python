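"""Diagonal similarity-zone accumulation, merging and clustering."""

import numpy as np
import pytest

from zonescan.lookup import build_lookup_table
from zonescan.scoring import encode_tuple
from zonescan.synthetic import MutationModel, mutate_homolog, random_proteome, random_protein
from zonescan.zones import (
    SearchParams,
    ZoneScanner,
    affine_gap_penalty,
    diagonal_index,
    scan_subject,
)


class TestDiagonalIndex:
    def test_origin(self, params):
        assert diagonal_index(0, 0, params) == params.max_subject_len

    def test_invariant_along_diagonal(self, params):
        assert diagonal_index(10, 3, params) == diagonal_index(11, 4, params)

    def test_adjacent_diagonals_differ(self, params):
        assert diagonal_index(10, 3, params) != diagonal_index(11, 3, params)

    def test_subject_too_long(self, params):
        with pytest.raises(ValueError, match="max_subject_len"):
            diagonal_index(0, params.max_subject_len, params)


class TestAffineGapPenalty:
    def test_zero_length_is_free(self, params):
        assert affine_gap_penalty(0, params) == 0

    def test_standard_values(self):
        p = SearchParams(gip=11, gep=1)
        assert affine_gap_penalty(5, p) == 16

    def test_monotone(self, params):
        pen = [affine_gap_penalty(n, params) for n in range(20)]
        assert pen == sorted(pen)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            affine_gap_penalty(-1, params)


def _self_diag_score(seq, matrix, k):
    """Running-sum oracle: the score a single-diagonal zone accumulates when
    a sequence is scanned against itself with exact tuple matches.

    The first match contributes the full k-tuple self score; every further
    1-step match adds only its last residue's self score (overlap k-1)."""
    idx = matrix.alphabet.encode(seq)
    first = int(matrix.scores[idx[:k], idx[:k]].sum())
    rest = int(matrix.scores[idx[k:], idx[k:]].sum())
    return first + rest


class TestScanSubject:
    def test_self_match_single_main_diagonal_zone(self, blosum62):
        seq = random_protein(300, np.random.default_rng(1))
        p = SearchParams(approx=1.0)
        table = build_lookup_table([seq], blosum62, k=5, approx=1.0)
        zones = scan_subject(seq, table, p)
        assert len(zones) == 1
        z = zones[0]
        assert z.query_index == 0
        assert z.diag_lo == z.diag_hi == p.max_subject_len  # main diagonal
        assert z.subj_lo == 0 and z.subj_hi == 299
        assert z.score == _self_diag_score(seq, blosum62, 5)

    def test_unrelated_subject_yields_nothing(self, blosum62):
        rng = np.random.default_rng(2)
        query = random_protein(200, rng)
        p = SearchParams(approx=1.0)
        table = build_lookup_table([query], blosum62, k=5, approx=1.0)
        # a subject sharing no 5-tuple neighborhood: low-complexity repeat
        zones = scan_subject("AC" * 100, table, p)
        assert zones == []

    def test_homolog_assigned_to_correct_query(self, blosum62):
        rng = np.random.default_rng(3)
        q1, q2 = random_protein(250, rng), random_protein(250, rng)
        subject, _ = mutate_homolog(q2, MutationModel(substitution_rate=0.1, seed=4))
        table = build_lookup_table([q1, q2], blosum62, k=5, approx=0.85)
        zones = scan_subject(subject, table, SearchParams())
        assert zones
        assert all(z.query_index == 1 for z in zones)

    def test_no_zone_crosses_query_boundary(self, blosum62):
        records = random_proteome(4, 150, seed=5)
        table = build_lookup_table(records, blosum62, k=5, approx=0.85)
        p = SearchParams()
        subject, _ = mutate_homolog(records[2].seq, MutationModel(substitution_rate=0.15, seed=6))
        for z in scan_subject(subject, table, p):
            start = int(table.catalog.starts[z.query_index])
            length = int(table.catalog.lengths[z.query_index])
            # query coordinates implied by the zone's diagonals and subject span
            q_lo = z.diag_lo - p.max_subject_len + z.subj_lo
            q_hi = z.diag_hi - p.max_subject_len + z.subj_hi
            assert q_lo >= start
            assert q_hi < start + length

    def test_reported_zones_reach_kthresh(self, blosum62):
        records = random_proteome(3, 200, seed=8)
        table = build_lookup_table(records, blosum62, k=5, approx=0.85)
        p = SearchParams(kthresh=25)
        subject, _ = mutate_homolog(records[0].seq, MutationModel(substitution_rate=0.2, seed=9))
        for z in scan_subject(subject, table, p):
            assert z.score >= p.kthresh

    def test_lazy_invalidation_matches_fresh_state(self, blosum62):
        """Scanning s1 then s2 with one scanner equals scanning s2 alone."""
        rng = np.random.default_rng(10)
        query = random_protein(250, rng)
        s1, _ = mutate_homolog(query, MutationModel(substitution_rate=0.1, seed=11))
        s2, _ = mutate_homolog(query, MutationModel(substitution_rate=0.25, seed=12))
        table = build_lookup_table([query], blosum62, k=5, approx=0.85)
        p = SearchParams()
        scanner = ZoneScanner(table, p)
        scanner.scan(s1)
        streamed = scanner.scan(s2)
        fresh = scan_subject(s2, table, p)
        assert streamed == fresh

    def test_subject_longer_than_limit_rejected(self, blosum62):
        table = build_lookup_table(["ACDEFGHIK"], blosum62, k=5)
        p = SearchParams(max_subject_len=50)
        with pytest.raises(ValueError, match="exceeds max_subject_len"):
            scan_subject("A" * 51, table, p)

    def test_entry_order_within_region_irrelevant(self, blosum62):
        """Zone results are invariant to shuffling entries inside regions."""
        records = random_proteome(3, 150, seed=20)
        table = build_lookup_table(records, blosum62, k=5, approx=0.85)
        subject, _ = mutate_homolog(records[1].seq, MutationModel(substitution_rate=0.15, seed=21))
        p = SearchParams()
        before = scan_subject(subject, table, p)
        rng = np.random.default_rng(22)
        for code_lo, code_hi in zip(table.offsets[:-1], table.offsets[1:]):
            lo, hi = int(code_lo), int(code_hi)
            if hi - lo > 1:
                perm = rng.permutation(hi - lo)
                table.entry_query[lo:hi] = table.entry_query[lo:hi][perm]
                table.entry_offset[lo:hi] = table.entry_offset[lo:hi][perm]
                table.entry_suffix[lo:hi] = table.entry_suffix[lo:hi][perm]
        after = scan_subject(subject, table, p)
        key = lambda z: (z.query_index, z.diag_lo, z.subj_lo)
        assert sorted(before, key=key) == sorted(after, key=key)


class TestZoneGrowth:
    def _table_for(self, query, blosum62, approx=1.0):
        return build_lookup_table([query], blosum62, k=5, approx=approx)

    def test_abutting_matches_sum_full_scores(self, blosum62):
        """Two matches at distance k on a diagonal: no overlap, no gap."""
        rng = np.random.default_rng(30)
        core = random_protein(10, rng)
        # query and subject share exactly this 10-mer, surrounded by
        # unrelated low-complexity context that creates no seeds
        query = core
        subject = core
        table = self._table_for(query, blosum62)
        p = SearchParams(kthresh=10)
        zones = scan_subject(subject, table, p)
        assert len(zones) == 1
        assert zones[0].score == _self_diag_score(core, blosum62, 5)

    def test_insertion_split_merges_with_mxshift(self, blosum62):
        """A 2-residue insertion splits the match across two diagonals that
        merge when mxshift >= 2 and stay separate at mxshift = 0."""
        rng = np.random.default_rng(31)
        left, right = random_protein(40, rng), random_protein(40, rng)
        query = left + right
        subject = left + random_protein(2, rng) + right
        table = self._table_for(query, blosum62)
        merged = scan_subject(subject, table, SearchParams(approx=1.0, mxshift=2))
        split = scan_subject(subject, table, SearchParams(approx=1.0, mxshift=0, kthresh=18))
        assert len(merged) == 1
        assert merged[0].diag_hi - merged[0].diag_lo == 2
        assert merged[0].subj_lo == 0 and merged[0].subj_hi == len(subject) - 1
        # without lateral search the two seeds stay on separate diagonals
        # until final clustering; disable clustering's reach via huge gip
        far = scan_subject(subject, table, SearchParams(approx=1.0, mxshift=0, gip=10**6))
        assert len(far) == 2

    def test_distant_match_starts_new_zone(self, blosum62):
        """A separation whose affine penalty exceeds the accumulated score
        starts an independent zone on the same diagonal; the final
        clustering then reunites the two collinear zones (their diagonal
        distance is zero, so the linking penalty is zero)."""
        rng = np.random.default_rng(32)
        block_a, block_b = random_protein(8, rng), random_protein(8, rng)
        query = block_a + random_protein(120, rng) + block_b
        subject = block_a + random_protein(120, rng) + block_b
        table = self._table_for(query, blosum62)
        p = SearchParams(approx=1.0, mxshift=0, gip=10**6, kthresh=10)
        scanner = ZoneScanner(table, p)
        zones = scanner.scan(subject)
        score_a = _self_diag_score(block_a, blosum62, 5)
        score_b = _self_diag_score(block_b, blosum62, 5)
        # before clustering: two independent hits with the per-block scores
        assert len(scanner._hits) == 2
        assert sorted(int(scanner._z_best[z]) for z in scanner._hits) == sorted(
            [score_a, score_b]
        )
        # after clustering: one merged zone spanning both blocks
        assert len(zones) == 1
        assert zones[0].subj_lo == 0 and zones[0].subj_hi == len(subject) - 1
        assert zones[0].score == score_a + score_b
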