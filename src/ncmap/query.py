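"""Candidate retrieval: sketch read windows, query both indices, emit regions.

For every read two 3N query variants are generated — the converted read and
the converted reverse complement — and both are looked up in both
orientation tables (four streams per read).  Because the conversion is
applied after reverse complementation, a reverse-strand read is only
recoverable through the reverse-complement table (forward variant) or the
forward table (reverse-complement variant); the mapping strand follows from
the combination.

Feature hits are accumulated per (target, window) and turned into candidate
regions wherever at least ``t`` features co-occur within a window range no
longer than the read's own window count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .index import (
    IndexParams,
    ReferenceIndex,
    kmer_hashes_positional,
    windows,
    _sketch_from_hashes,
    _SENTINEL as _HASH_SENTINEL,
)
from .seqcore import ConversionScheme, convert_3n, encode, reverse_complement

__all__ = [
    "QueryParams",
    "CandidateRegion",
    "query_variants",
    "collect_hits",
    "select_candidates",
    "pair_candidates",
    "find_candidates",
]

_U64 = np.uint64


@dataclass(frozen=True)
class QueryParams:
    """Candidate-selection parameters.

    t: minimum number of feature hits required for a candidate region.
    max_candidates_per_read: cap on emitted candidates, ranked by hit score.
    max_insert: maximal fragment length considered when accumulating
    paired-end scores across neighbouring regions (bp).
    """

    t: int = 4
    max_candidates_per_read: int = 16
    max_insert: int = 1000

    def __post_init__(self):
        if self.t < 1 or self.max_candidates_per_read < 1:
            raise ValueError("t and max_candidates_per_read must be >= 1")


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate mapping region for one read.

    Window coordinates (``window_first``..``window_last``, inclusive) are in
    the frame of the table that produced the hits (``frame`` is ``"fwd"``
    or ``"rev"``); ``gstart``/``gend`` give the corresponding un-padded
    forward-strand genomic span once resolved.  ``strand`` is the deduced
    mapping strand of the read.
    """

    target_id: int
    window_first: int
    window_last: int
    hit_score: int
    strand: str = "+"
    frame: str = "fwd"
    gstart: int = -1
    gend: int = -1


def query_variants(read_seq: str, scheme: ConversionScheme) -> tuple[str, str]:
    """The two 3N query variants: converted read, converted revcomp."""
    return convert_3n(read_seq, scheme), convert_3n(reverse_complement(read_seq), scheme)


def _window_feature_keys(query_seq: str, index: ReferenceIndex) -> np.ndarray:
    """Concatenated h2 bucket keys over all window sketches of the query.

    Reads shorter than ``w`` form a single window comprising the whole
    read.  Both orientation tables share one h2, so keys are computed once
    per query variant.
    """
    params = index.params
    codes = encode(query_seq)
    H = kmer_hashes_positional(codes, params)  # one pass; windows slice it
    n = len(H)
    keys: list[np.ndarray] = []
    for _, off, wseq in windows(query_seq, params):
        h1 = H[off : min(off + len(wseq) - params.k + 1, n)]
        h1 = h1[h1 != _HASH_SENTINEL]
        sk = _sketch_from_hashes(h1, params.s)
        if len(sk):
            keys.append(index.forward_table.h2(sk))
    if not keys:
        return np.empty(0, dtype=_U64)
    return np.concatenate(keys)


def collect_hits(query_seq: str, index: ReferenceIndex, orientation: str = "forward") -> np.ndarray:
    """All feature hits of a query against one orientation table.

    Returns packed (target_id << 32 | window_id) locations sorted ascending
    by (target_id, window_id), duplicates retained — each hit counts once
    per contributing feature.  Equivalent to merging the per-feature sorted
    location lists.
    """
    table = index.forward_table if orientation == "forward" else index.reverse_table
    keys = _window_feature_keys(query_seq, index)
    return _hits_for_keys(keys, table)


def _hits_for_keys(keys: np.ndarray, table) -> np.ndarray:
    return table.hits_for_keys(keys)


def n_read_windows(read_len: int, params: IndexParams) -> int:
    if read_len < params.k:
        return 0
    return (read_len - params.k) // params.stride + 1


def select_candidates(
    hits: np.ndarray,
    n_windows: int,
    qp: QueryParams,
    strand: str = "+",
    frame: str = "fwd",
) -> list[CandidateRegion]:
    """Sliding scan over sorted hits → candidate regions with >= t hits.

    For every placement of a window interval spanning at most ``n_windows``
    windows, the contained hits are counted; qualifying (>= t) placements
    are tightened to their first/last hit windows, overlapping placements
    merged keeping the highest-scoring one, and the result ranked by
    (hit_score desc, target asc, window_first asc) and truncated to
    ``max_candidates_per_read``.
    """
    if len(hits) == 0 or n_windows < 1:
        return []
    out: list[CandidateRegion] = []
    for tid, placements in qualifying_placements(hits, n_windows, qp.t):
        out.extend(
            CandidateRegion(int(tid), f, l, c, strand=strand, frame=frame)
            for f, l, c in _merge_placements(placements)
        )
    out.sort(key=lambda c: (-c.hit_score, c.target_id, c.window_first))
    return out[: qp.max_candidates_per_read]


def qualifying_placements(
    hits: np.ndarray, n_windows: int, t: int
) -> list[tuple[int, list[tuple[int, int, int]]]]:
    """Per target: tight (window_first, window_last, hit_count) placements.

    A placement anchors a window interval of span <= ``n_windows`` at a hit
    window and counts the hits it contains; only placements with >= ``t``
    hits qualify.  The qualifying set is monotone in ``t``: raising the
    threshold can only remove placements.
    """
    hits = np.asarray(hits, dtype=_U64)
    if len(hits) < t:
        return []
    targets = (hits >> _U64(32)).astype(np.int64)
    wins = (hits & _U64(0xFFFFFFFF)).astype(np.int64)
    out = []
    for tid in np.unique(targets):
        w = wins[targets == tid]  # sorted
        if len(w) < t:
            continue
        left = np.flatnonzero(np.diff(w, prepend=-1) > 0)  # distinct left endpoints
        his = np.searchsorted(w, w[left] + n_windows - 1, side="right")
        counts = his - left
        sel = counts >= t
        placements = [
            (int(a), int(b), int(c))
            for a, b, c in zip(w[left[sel]], w[his[sel] - 1], counts[sel])
        ]
        out.append((int(tid), placements))
    return out


def _merge_placements(placements: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Merge overlapping (first, last, count) ranges, keeping the best.

    Best within an overlap chain = highest count, then leftmost, then
    shortest.  Placements are tight (endpoints are hit windows).
    """
    if not placements:
        return []
    placements.sort()
    merged: list[list] = []  # [chain_first, chain_last, best_placement]
    for p in placements:
        if merged and p[0] <= merged[-1][1]:
            chain = merged[-1]
            chain[1] = max(chain[1], p[1])
            if (-p[2], p[0], p[1]) < (-chain[2][2], chain[2][0], chain[2][1]):
                chain[2] = p
        else:
            merged.append([p[0], p[1], p])
    return [chain[2] for chain in merged]


def _resolve_span(c: CandidateRegion, index: ReferenceIndex, read_len: int) -> CandidateRegion:
    """Fill forward-strand genomic coordinates for a candidate.

    Reverse-table window IDs count from the 3′ end of the forward target and
    are mirrored here.  The span is the tight window span; padding for
    alignment is applied later by the region extractor.
    """
    p = index.params
    L = index.target_lengths[c.target_id]
    s = c.window_first * p.stride
    e = min(c.window_last * p.stride + p.w, L)
    if c.frame == "rev":
        s, e = L - e, L - s
    return replace(c, gstart=s, gend=e)


_COMBOS = (
    # (variant index, orientation, deduced mapping strand)
    (0, "forward", "+"),
    (0, "reverse", "-"),
    (1, "forward", "-"),
    (1, "reverse", "+"),
)


def find_candidates(read_seq: str, index: ReferenceIndex, qp: QueryParams) -> list[CandidateRegion]:
    """Full candidate retrieval for one read, deduplicated, forward frame.

    Queries both 3N variants against both tables, selects candidates per
    stream, resolves genomic coordinates, and removes duplicates: same
    (target, strand) candidates with overlapping spans are collapsed to the
    highest-scoring one.  Output ranked by (hit_score desc, target,
    gstart, strand) and truncated to ``max_candidates_per_read``.
    """
    params = index.params
    if len(read_seq) < params.k:
        return []
    nw = n_read_windows(len(read_seq), params)
    variants = query_variants(read_seq, index.scheme)
    keys = [_window_feature_keys(v, index) for v in variants]
    cands: list[CandidateRegion] = []
    for vi, orientation, strand in _COMBOS:
        table = index.forward_table if orientation == "forward" else index.reverse_table
        hits = _hits_for_keys(keys[vi], table)
        frame = "fwd" if orientation == "forward" else "rev"
        for c in select_candidates(hits, nw, qp, strand=strand, frame=frame):
            cands.append(_resolve_span(c, index, len(read_seq)))
    return _dedup_candidates(cands, qp)


def _dedup_candidates(cands: list[CandidateRegion], qp: QueryParams) -> list[CandidateRegion]:
    by_group: dict[tuple[int, str], list[CandidateRegion]] = {}
    for c in cands:
        by_group.setdefault((c.target_id, c.strand), []).append(c)
    kept: list[CandidateRegion] = []
    for group in by_group.values():
        group.sort(key=lambda c: (c.gstart, c.gend))
        chain: list[CandidateRegion] = []
        chain_end = -1
        for c in group:
            if chain and c.gstart < chain_end:
                chain.append(c)
                chain_end = max(chain_end, c.gend)
            else:
                if chain:
                    kept.append(_best_of(chain))
                chain = [c]
                chain_end = c.gend
        if chain:
            kept.append(_best_of(chain))
    kept.sort(key=lambda c: (-c.hit_score, c.target_id, c.gstart, c.strand))
    return kept[: qp.max_candidates_per_read]


def _best_of(chain: list[CandidateRegion]) -> CandidateRegion:
    return min(chain, key=lambda c: (-c.hit_score, c.gstart, c.gend))


def pair_candidates(
    cands_r1: Sequence[CandidateRegion],
    cands_r2: Sequence[CandidateRegion],
    qp: QueryParams,
) -> list[tuple[CandidateRegion | None, CandidateRegion | None, int]]:
    """Accumulate paired-end scores across mate candidates.

    Mate candidates on the same target with opposite strands whose combined
    span fits within ``max_insert`` are paired and score the sum of the two
    hit scores.  Candidates of either mate that pair with nothing are kept
    as singletons with their own score.  The result is ranked by combined
    score (descending) with deterministic tie-breaks and is symmetric under
    swapping the mates (with entries transposed).
    """
    pairs: list[tuple[CandidateRegion | None, CandidateRegion | None, int]] = []
    paired1: set[int] = set()
    paired2: set[int] = set()
    for i, c1 in enumerate(cands_r1):
        for j, c2 in enumerate(cands_r2):
            if c1.target_id != c2.target_id or c1.strand == c2.strand:
                continue
            span = max(c1.gend, c2.gend) - min(c1.gstart, c2.gstart)
            if span <= qp.max_insert:
                pairs.append((c1, c2, c1.hit_score + c2.hit_score))
                paired1.add(i)
                paired2.add(j)
    for i, c1 in enumerate(cands_r1):
        if i not in paired1:
            pairs.append((c1, None, c1.hit_score))
    for j, c2 in enumerate(cands_r2):
        if j not in paired2:
            pairs.append((None, c2, c2.hit_score))
    pairs.sort(key=lambda p: (-p[2], _ckey(p[0]), _ckey(p[1])))
    return pairs


def _ckey(c: CandidateRegion | None):
    if c is None:
        return (1, 0, 0, "")
    return (0, c.target_id, c.gstart, c.strand)
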