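"""End-to-end search orchestration.

Builds the lookup table once over the query set, streams subject records
through the zone scanner, aligns merged zones within extended bands, and
post-processes: score filter, repeat filter, optional remote-segment
merging, Karlin-Altschul statistics, ranking and truncation to ``rpq``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

from dataclasses import replace

from .banded import banded_align, extend_band
from .io import SequenceRecord, read_fasta, write_results
from .lookup import build_lookup_table
from .postprocess import (
    attach_statistics,
    attach_super_statistics,
    filter_by_score,
    filter_long_repeats,
    get_karlin_params,
    merge_remote_segments,
    rank_and_report,
)
from .scoring import load_matrix
from .zones import SearchParams, ZoneScanner

logger = logging.getLogger(__name__)


def _align_band(query_idx, subject_idx, band, matrix, params, query_id, subject_id):
    """All non-overlapping (in subject) local alignments within a band.

    A merged zone can cover several similarity segments separated by
    dissimilar stretches that a single local alignment will not cross; after
    the best alignment is extracted the band is split at its subject span
    and the remainders are aligned recursively.  Secondary alignments are
    kept only when they reach the zone detection threshold."""
    out = []
    stack = [(band, True)]
    while stack:
        b, primary = stack.pop()
        if b.s_lo > b.s_hi or b.q_lo > b.q_hi:
            continue
        aln = banded_align(
            query_idx, subject_idx, b, matrix, params,
            query_id=query_id, subject_id=subject_id,
        )
        if aln is None:
            continue
        if not primary and aln.sw_score < params.kthresh:
            continue
        out.append(aln)
        stack.append((replace(b, s_hi=aln.s_start - 1), False))
        stack.append((replace(b, s_lo=aln.s_end), False))
    return out


@dataclass
class RunConfig:
    query_path: str
    subject_path: str
    output_path: str | None = None  # None -> stdout
    omode: str = "NCBI_M8"
    matrix: str = "BLOSUM62"
    params: SearchParams = field(default_factory=SearchParams)


def search_records(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    params: SearchParams | None = None,
    matrix=None,
):
    """Run the full pipeline on in-memory records; returns the ranked hits.

    This is the library entry point: the CLI wraps it with FASTA reading
    and result formatting.
    """
    params = params or SearchParams()
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    elif isinstance(matrix, str):
        matrix = load_matrix(matrix)

    table = build_lookup_table(queries, matrix, k=params.k, approx=params.approx)
    scanner = ZoneScanner(table, params)
    q_lengths = {i: len(q.seq) for i, q in enumerate(queries)}

    alignments = []
    n_subject_residues = 0
    n_zones = 0
    for subject in subjects:
        n_subject_residues += len(subject.seq)
        zones = scanner.scan(subject.seq)
        n_zones += len(zones)
        per_pair = []
        for zone in zones:
            qi = zone.query_index
            band = extend_band(
                zone, params, q_lengths[qi], len(subject.seq),
                int(table.catalog.starts[qi]),
            )
            alns = _align_band(
                table.catalog.encoded[qi],
                matrix.alphabet.encode(subject.seq),
                band,
                matrix,
                params,
                queries[qi].id,
                subject.id,
            )
            for aln in alns:
                aln.query_index = qi
            per_pair.extend(alns)
        alignments.extend(per_pair)

    alignments = filter_by_score(alignments, params.min_score)

    # repeat filter and optional remote merge operate per query/subject pair
    by_pair: dict[tuple[int, str], list] = {}
    for a in alignments:
        by_pair.setdefault((a.query_index, a.subject_id), []).append(a)
    hits = []
    for key in sorted(by_pair, key=lambda k: (k[0], k[1])):
        group = by_pair[key]
        # overlapping bands from distinct zones can rediscover a segment
        seen = set()
        deduped = []
        for a in group:
            sig = (a.q_start, a.q_end, a.s_start, a.s_end, a.sw_score)
            if sig not in seen:
                seen.add(sig)
                deduped.append(a)
        group = deduped
        if params.repeat_filter:
            group = filter_long_repeats(group)
        if params.merge_remote:
            hits.extend(merge_remote_segments(group, params))
        else:
            hits.extend(group)

    kp = get_karlin_params(matrix, params.gip, params.gep)
    plain = [h for h in hits if hasattr(h, "aligned_length")]
    supers = [h for h in hits if not hasattr(h, "aligned_length")]
    attach_statistics(plain, q_lengths, n_subject_residues, kp)
    attach_super_statistics(supers, q_lengths, n_subject_residues, kp)

    ranked = rank_and_report(hits, params)
    logger.info(
        "search: %d queries, %d subjects (%d residues), %d lookup entries, "
        "%d zones created, %d zones merged, %d merged zones aligned, "
        "%d alignments, %d hits reported",
        len(queries), len(subjects), n_subject_residues, table.total_entries,
        scanner.zones_created, scanner.zones_merged, n_zones,
        len(alignments), len(ranked),
    )
    return ranked


def run_search(config: RunConfig) -> int:
    """File-to-file search; returns a process exit status."""
    try:
        queries = read_fasta(config.query_path)
        try:
            subjects = read_fasta(config.subject_path)
        except ValueError:
            subjects = []  # an empty subject set is a valid (empty) search
        hits = search_records(queries, subjects, config.params, config.matrix)
        qmap = {q.id: q for q in queries}
        smap = {s.id: s for s in subjects}
        if config.output_path:
            with open(config.output_path, "w") as fh:
                write_results(hits, config.omode, fh, qmap, smap)
        else:
            write_results(hits, config.omode, sys.stdout, qmap, smap)
    except Exception:
        logger.exception("search failed")
        return 1
    return 0
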