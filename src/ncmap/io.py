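"""Standard-format input/output and pipeline orchestration.

FASTA/FASTQ parsing goes through Biopython; SAM emission and parsing go
through pysam so that output is standards-conformant by construction.
Mapped records carry HISAT-3N-compatible extra tags: ``Yf:i`` (number of
identified conversions) and ``YZ:A`` (alignment strand), plus ``NM``
(edit distance), ``NH`` (number of reported locations) and ``ZP:f``
(filter probability, when the random-forest filter ran).
"""

from __future__ import annotations

import gzip
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .align import cigar_to_m
from .index import ReferenceIndex
from .pipeline import MappingRecord, MappingResult, map_reads
from .seqcore import reverse_complement
from .simulator import SimRead

__all__ = [
    "read_fasta",
    "read_fastq",
    "write_sam",
    "read_sam_records",
    "write_custom",
    "run_pipeline",
]

DEFAULT_MAX_PROPER_INSERT = 1000


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def read_fastq(path: str, mate: int = 0) -> list[SimRead]:
    """Read a FASTQ file into (read_id, mate, seq) triples.

    Trailing ``/1`` / ``/2`` suffixes are stripped from read names; ``mate``
    labels every read of the file (0 = single-end).
    """
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            rid = rec.id
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            out.append(SimRead(rid, mate, str(rec.seq).upper()))
    return out


def _sam_header(index: ReferenceIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": n, "LN": L}
                for n, L in zip(index.target_names, index.target_lengths)
            ],
            "PG": [{"ID": "ncmap", "PN": "ncmap"}],
        }
    )


def write_sam(
    records: Sequence[MappingRecord],
    index: ReferenceIndex,
    path: str,
    cigar_dialect: str = "eqx",
    max_proper_insert: int = DEFAULT_MAX_PROPER_INSERT,
) -> None:
    """Write mapping records as SAM.

    Every input read appears exactly once as mapped (first record primary,
    additional locations flagged secondary 0x100) or as unmapped (0x4).
    Mate fields and the proper-pair flag are derived from the primary
    mapping of the other mate.
    """
    header = _sam_header(index)
    primary: dict[tuple[str, int], MappingRecord] = {
        (r.read_id, r.mate): r for r in records if r.is_primary
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            flag = 0
            paired = r.mate in (1, 2)
            mate_rec = primary.get((r.read_id, 3 - r.mate)) if paired else None
            if paired:
                flag |= 0x1
                flag |= 0x40 if r.mate == 1 else 0x80
                if mate_rec is None or not mate_rec.mapped:
                    flag |= 0x8
                elif mate_rec.strand == "-":
                    flag |= 0x20
            if not r.mapped:
                flag |= 0x4
                seg.flag = flag
                seg.query_sequence = r.seq or None
                out.write(seg)
                continue
            if r.strand == "-":
                flag |= 0x10
            if not r.is_primary:
                flag |= 0x100
            proper = (
                paired
                and mate_rec is not None
                and mate_rec.mapped
                and mate_rec.target_id == r.target_id
                and mate_rec.strand != r.strand
                and max(r.gend, mate_rec.gend) - min(r.gstart, mate_rec.gstart)
                <= max_proper_insert
            )
            if proper and r.is_primary:
                flag |= 0x2
            seg.flag = flag
            seg.reference_id = r.target_id
            seg.reference_start = r.gstart
            seg.mapping_quality = 255
            seg.cigarstring = r.cigar if cigar_dialect == "eqx" else cigar_to_m(r.cigar)
            seg.query_sequence = r.seq if r.strand == "+" else reverse_complement(r.seq)
            if paired and mate_rec is not None and mate_rec.mapped:
                seg.next_reference_id = mate_rec.target_id
                seg.next_reference_start = mate_rec.gstart
                if mate_rec.target_id == r.target_id:
                    lo = min(r.gstart, mate_rec.gstart)
                    hi = max(r.gend, mate_rec.gend)
                    seg.template_length = (hi - lo) if r.gstart <= mate_rec.gstart else -(hi - lo)
            tags = [
                ("NM", r.edit_distance, "i"),
                ("NH", r.multiplicity, "i"),
                ("Yf", r.n_conversions, "i"),
                ("YZ", r.strand, "A"),
            ]
            if r.p_positive is not None:
                tags.append(("ZP", float(r.p_positive), "f"))
            seg.set_tags(tags)
            out.write(seg)


def read_sam_records(path: str):
    """Parse SAM back into lightweight records usable by the evaluator."""

    class _Rec:
        __slots__ = ("read_id", "mate", "target_id", "gstart", "gend", "strand", "is_primary")

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            r = _Rec()
            r.read_id = seg.query_name
            r.mate = 1 if seg.is_read1 else 2 if seg.is_read2 else 0
            if seg.is_unmapped:
                r.target_id = -1
                r.gstart = r.gend = -1
                r.strand = "."
                r.is_primary = True
            else:
                r.target_id = seg.reference_id
                r.gstart = seg.reference_start
                r.gend = seg.reference_end
                r.strand = "-" if seg.is_reverse else "+"
                r.is_primary = not seg.is_secondary
            out.append(r)
    return out


def write_custom(records: Sequence[MappingRecord], index: ReferenceIndex, path: str) -> None:
    """Custom tab-separated output with a nucleotide-conversion table.

    Section one lists kept mappings (read, mate, target, start, end,
    strand, score, conversion count); section two lists, per mapping, the
    0-based reference positions of the identified conversions.
    """
    with open(path, "w") as fh:
        fh.write("#ncmap\t1\n")
        fh.write("#read_id\tmate\ttarget\tstart\tend\tstrand\tscore\tn_conversions\n")
        mapped = [r for r in records if r.mapped]
        for r in mapped:
            fh.write(
                f"{r.read_id}\t{r.mate}\t{index.target_names[r.target_id]}\t"
                f"{r.gstart}\t{r.gend}\t{r.strand}\t{r.score:.4f}\t{r.n_conversions}\n"
            )
        fh.write("#conversion_table\n")
        fh.write("#read_id\tmate\ttarget\tpositions\n")
        for r in mapped:
            pos = ",".join(map(str, r.conv_positions)) if r.conv_positions else "-"
            fh.write(f"{r.read_id}\t{r.mate}\t{index.target_names[r.target_id]}\t{pos}\n")


def run_pipeline(
    index: ReferenceIndex,
    reads: Iterable,
    out_path: str,
    out_format: str = "sam",
    cigar_dialect: str = "eqx",
    **map_kwargs,
) -> MappingResult:
    """Map reads and write results; returns the in-memory result + report."""
    result = map_reads(index, list(reads), **map_kwargs)
    if out_format == "sam":
        write_sam(result.records, index, out_path, cigar_dialect=cigar_dialect)
    elif out_format == "tsv":
        write_custom(result.records, index, out_path)
    else:
        raise ValueError(f"unknown output format {out_format!r}")
    return result
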