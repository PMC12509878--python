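"""Semi-global (infix) alignment of 3N reads against candidate regions.

Alignment happens in the reduced three-letter alphabet, so true chemical
conversions are cost-free and only sequencing errors and genuine variants
count towards the edit distance.  Gaps at either end of the *region* are
free; the query is always consumed entirely.  Unit costs (match 0,
mismatch/insertion/deletion 1).  The dynamic programming itself is
delegated to edlib; this module owns placement tie-breaking, CIGAR
handling and the projection of region-relative alignments back onto
forward-strand genomic coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

__all__ = [
    "AlignmentResult",
    "align_semi_global",
    "project_to_genome",
    "cigar_ops",
    "cigar_to_m",
    "reverse_cigar",
]

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one semi-global alignment.

    ``region_start``/``region_end`` delimit the aligned reference span
    (0-based, half-open) within the candidate region.  ``cigar`` is in the
    extended =/X/I/D dialect, query-oriented.  ``score`` is the normalised
    alignment score 1 − edit_distance / query_length, in [0, 1].
    """

    edit_distance: int
    region_start: int
    region_end: int
    cigar: str
    query_len: int

    @property
    def score(self) -> float:
        return 1.0 - self.edit_distance / self.query_len


def align_semi_global(
    query_3n: str, region_3n: str, max_dist: int | None = None
) -> AlignmentResult | None:
    """Best infix alignment of ``query_3n`` inside ``region_3n``.

    Among equal-distance placements the leftmost (smallest region start) is
    returned.  ``max_dist`` bounds the accepted edit distance; alignments
    worse than that return ``None``.  Empty inputs are an error.
    """
    if not query_3n or not region_3n:
        raise ValueError("empty query or region")
    # exact-infix fast path (also guarantees leftmost placement at distance 0)
    pos = region_3n.find(query_3n)
    if pos >= 0:
        return AlignmentResult(0, pos, pos + len(query_3n), f"{len(query_3n)}=", len(query_3n))
    k = -1 if max_dist is None else max_dist
    loc = edlib.align(query_3n, region_3n, mode="HW", task="locations", k=k)
    if loc["editDistance"] < 0:
        return None
    start, end = min(loc["locations"])  # leftmost placement; end is inclusive
    if start is None:
        start = 0
    sub = region_3n[start : end + 1]
    path = edlib.align(query_3n, sub, mode="NW", task="path")
    return AlignmentResult(
        int(loc["editDistance"]), int(start), int(end) + 1, path["cigar"], len(query_3n)
    )


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def _ops_to_str(ops: list[tuple[int, str]]) -> str:
    # merge adjacent equal ops
    out: list[tuple[int, str]] = []
    for n, op in ops:
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)


def cigar_to_m(cigar: str) -> str:
    """Collapse the =/X dialect into the classic M dialect."""
    return _ops_to_str([(n, "M" if op in "=X" else op) for n, op in cigar_ops(cigar)])


def reverse_cigar(cigar: str) -> str:
    return _ops_to_str(list(reversed(cigar_ops(cigar))))


def cigar_lengths(cigar: str) -> tuple[int, int]:
    """(query bases consumed, reference bases consumed)."""
    q = r = 0
    for n, op in cigar_ops(cigar):
        if op in "=XM":
            q += n
            r += n
        elif op == "I":
            q += n
        elif op == "D":
            r += n
    return q, r


def project_to_genome(
    result: AlignmentResult,
    target_id: int,
    region_offset: int,
    region_len: int,
    strand: str,
    target_len: int,
    mirror: bool | None = None,
) -> tuple[int, int, int, str, str]:
    """Map a region-relative alignment to forward-strand genomic coordinates.

    When the alignment was computed against the reverse complement of the
    extracted region (``mirror``; by default assumed for '−'-strand
    mappings), coordinates are mirrored and the CIGAR reversed: the
    returned record always describes the forward reference strand (SAM
    convention).  Returns (target_id, genomic_start, genomic_end, strand,
    forward-frame cigar).
    """
    if mirror is None:
        mirror = strand == "-"
    if not mirror:
        gstart = region_offset + result.region_start
        gend = region_offset + result.region_end
        cig = result.cigar
    else:
        gstart = region_offset + (region_len - result.region_end)
        gend = region_offset + (region_len - result.region_start)
        cig = reverse_cigar(result.cigar)
    if gstart < 0 or gend > target_len:
        raise ValueError(
            f"projected span [{gstart},{gend}) exceeds target of length {target_len}"
        )
    return target_id, gstart, gend, strand, cig
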