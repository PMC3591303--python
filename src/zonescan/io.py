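"""FASTA input and result writers (TEXT, TAB, TABX, NCBI m8/m9)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

OUTPUT_MODES = ("TEXT", "TAB", "TABX", "NCBI_M8", "NCBI_M9")


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""


def read_fasta(path) -> list[SequenceRecord]:
    """Ordered FASTA records; residues uppercased, empty records skipped
    with a warning.  Raises if the file yields no usable records."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("skipping empty sequence record '%s'", rec.id)
            continue
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    if not records:
        raise ValueError(f"no parseable sequence records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def _fmt_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    if e < 1e-99:
        return f"{e:.0e}"
    if e < 0.001:
        return f"{e:.2e}"
    return f"{e:.3g}"


M8_HEADER = (
    "# Fields: query id, subject id, % identity, alignment length, mismatches, "
    "gap openings, q. start, q. end, s. start, s. end, evalue, bit score"
)


def _m8_line(h) -> str:
    # internal 0-based half-open -> 1-based inclusive
    gaps = getattr(h, "gap_openings", 0)
    length = getattr(h, "aligned_length", None)
    if length is None:  # super-alignments: span-based length
        length = max(h.q_end - h.q_start, h.s_end - h.s_start)
    ident = getattr(h, "identities", None)
    mism = getattr(h, "mismatches", None)
    if ident is None:
        ident = sum(m.identities for m in h.members)
        mism = sum(m.mismatches for m in h.members)
        gaps = sum(m.gap_openings for m in h.members)
        length = sum(m.aligned_length for m in h.members)
    pct = 100.0 * ident / length if length else 0.0
    return "\t".join(
        [
            h.query_id,
            h.subject_id,
            f"{pct:.2f}",
            str(length),
            str(mism),
            str(gaps),
            str(h.q_start + 1),
            str(h.q_end),
            str(h.s_start + 1),
            str(h.s_end),
            _fmt_evalue(h.evalue if h.evalue is not None else float("nan")),
            f"{h.bit_score:.1f}" if h.bit_score is not None else "NA",
        ]
    )


def _tab_line(h) -> str:
    return "\t".join(
        [
            h.query_id,
            h.subject_id,
            str(int(h.sw_score)),
            _fmt_evalue(h.evalue if h.evalue is not None else float("nan")),
            str(h.q_start + 1),
            str(h.q_end),
            str(h.s_start + 1),
            str(h.s_end),
        ]
    )


def _tabx_line(h) -> str:
    ident = getattr(h, "identities", 0)
    length = getattr(h, "aligned_length", 0) or 1
    return _tab_line(h) + "\t" + "\t".join(
        [
            f"{100.0 * ident / length:.2f}",
            str(length),
            str(getattr(h, "gap_openings", 0)),
        ]
    )


def _render_text(h, queries=None, subjects=None) -> str:
    score_line = f"  Score: {int(h.sw_score)}"
    if h.evalue is not None:
        score_line += f"  E-value: {_fmt_evalue(h.evalue)}"
    if h.bit_score is not None:
        score_line += f"  Bits: {h.bit_score:.1f}"
    lines = [
        f"Query: {h.query_id}  Subject: {h.subject_id}",
        score_line,
        f"  Query range: {h.q_start + 1}-{h.q_end}  Subject range: {h.s_start + 1}-{h.s_end}",
    ]
    if hasattr(h, "identities") and h.aligned_length:
        lines.append(
            f"  Identities: {h.identities}/{h.aligned_length} ({h.pct_identity:.1f}%), "
            f"mismatches: {h.mismatches}, gap openings: {h.gap_openings}"
        )
    if queries is not None and subjects is not None and hasattr(h, "path"):
        q = queries[h.query_id].seq
        s = subjects[h.subject_id].seq
        qa, sa, mid = [], [], []
        qp, sp = h.q_start, h.s_start
        for op, n in h.path:
            for _ in range(n):
                if op == "M":
                    qa.append(q[qp]); sa.append(s[sp])
                    mid.append("|" if q[qp] == s[sp] else " ")
                    qp += 1; sp += 1
                elif op == "I":
                    qa.append(q[qp]); sa.append("-"); mid.append(" "); qp += 1
                else:
                    qa.append("-"); sa.append(s[sp]); mid.append(" "); sp += 1
        for off in range(0, len(qa), 60):
            lines.append("  Q " + "".join(qa[off : off + 60]))
            lines.append("    " + "".join(mid[off : off + 60]))
            lines.append("  S " + "".join(sa[off : off + 60]))
    return "\n".join(lines) + "\n"


def write_results(hits, omode: str, stream, queries=None, subjects=None) -> None:
    """Write finalized hits (E-values attached) in the requested format."""
    omode = omode.upper()
    if omode not in OUTPUT_MODES:
        raise ValueError(f"unknown output mode '{omode}'; choose from {OUTPUT_MODES}")
    if omode == "NCBI_M9":
        stream.write("# zonescan protein similarity search\n")
        stream.write(M8_HEADER + "\n")
    for h in hits:
        if omode in ("NCBI_M8", "NCBI_M9"):
            stream.write(_m8_line(h) + "\n")
        elif omode == "TAB":
            stream.write(_tab_line(h) + "\n")
        elif omode == "TABX":
            stream.write(_tabx_line(h) + "\n")
        else:
            stream.write(_render_text(h, queries, subjects) + "\n")
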