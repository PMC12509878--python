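"""End-to-end read mapping: query → align → MSA filter → records.

The five stages run in order: candidate retrieval against both 3N indices,
semi-global alignment of every candidate, grouping of alignments by
candidate reference region, MSA statistics + filtering, and record
assembly.  Reads are processed in batches through the stateless
query/alignment stages; region grouping and filtering happen only after
all reads are aligned, so results are independent of the batch size.

Which 3N orientation is aligned follows the query combination that
produced the candidate: candidates from the reverse-complement table are
aligned in that table's frame and mirrored back to forward coordinates.
The index frame also fixes ``conv_strand`` — the strand the chemistry
acted on — which the MSA stage needs to tell conversions from errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import align_semi_global, project_to_genome
from .index import ReferenceIndex
from .msa import (
    AlignedRead,
    ForestModel,
    build_msa,
    conversion_positions,
    count_conversions,
    feature_vector,
    filter_region,
    global_stats,
    rf_classify_many,
    MAX_MSA_READS,
    MSAProfile,
)
from .query import CandidateRegion, QueryParams, find_candidates, pair_candidates
from .seqcore import ConversionScheme, convert_3n, reverse_complement

__all__ = ["MappingRecord", "MappingResult", "map_reads", "collect_alignments", "finalize_mappings", "train_filter"]

DEFAULT_MIN_SCORE = 0.8


@dataclass
class MappingRecord:
    """One reported mapping (or an unmapped placeholder, target_id = −1)."""

    read_id: str
    mate: int
    target_id: int
    gstart: int
    gend: int
    strand: str
    cigar: str
    score: float
    edit_distance: int
    n_conversions: int
    conv_positions: list[int] = field(default_factory=list)
    p_positive: float | None = None
    is_primary: bool = True
    multiplicity: int = 0
    seq: str = ""

    @property
    def mapped(self) -> bool:
        return self.target_id >= 0


@dataclass
class AlignmentSet:
    """Intermediate state after the alignment stage, before filtering."""

    groups: dict[tuple[int, int], list[AlignedRead]]
    read_keys: list[tuple[str, int]]
    read_seqs: dict[tuple[str, int], str]
    n_candidates: int = 0
    n_alignments: int = 0


@dataclass
class MappingResult:
    records: list[MappingRecord]
    report: dict
    features: list[tuple] | None = None  # (read_id, mate, tid, gstart, gend, strand, vector)


def _variant_for(c: CandidateRegion) -> str:
    # which 3N read variant produced this candidate (see query._COMBOS)
    return "fwd" if (c.strand == "+") == (c.frame == "fwd") else "rc"


def _align_candidate(
    read_seq: str,
    c: CandidateRegion,
    index: ReferenceIndex,
    max_dist: int,
) -> AlignedRead | None:
    """Align one candidate in both chemistry-consistent 3N orientations.

    A mapping strand is compatible with two conversion layouts: the read
    may stem from the converted strand itself or from its complement (the
    second mate of a converted fragment).  Only the matching layout makes
    conversions cost-free, so both are aligned and the better one kept;
    ties go to the index frame that produced the candidate.
    """
    ref = index.target_seqs[c.target_id]
    L = len(ref)
    pad = len(read_seq)
    rs = max(0, c.gstart - pad)
    re_ = min(L, c.gend + pad)
    region = ref[rs:re_]
    scheme = index.scheme
    q_fwd = convert_3n(read_seq, scheme)
    q_rc = convert_3n(reverse_complement(read_seq), scheme)
    frames = ("fwd", "rev") if c.frame == "fwd" else ("rev", "fwd")
    best: AlignedRead | None = None
    for frame in frames:
        # the query variant consistent with (mapping strand, frame)
        q3n = q_fwd if (c.strand == "+") == (frame == "fwd") else q_rc
        r3n = convert_3n(region if frame == "fwd" else reverse_complement(region), scheme)
        res = align_semi_global(q3n, r3n, max_dist=max_dist)
        if res is None:
            continue
        _, gstart, gend, _, cigar = project_to_genome(
            res, c.target_id, rs, len(region), c.strand, L, mirror=(frame == "rev")
        )
        aln = AlignedRead(
            read_id="",  # filled by caller
            mate=0,
            seq=read_seq,
            strand=c.strand,
            target_id=c.target_id,
            gstart=gstart,
            gend=gend,
            cigar=cigar,
            score=res.score,
            edit_distance=res.edit_distance,
            conv_strand="+" if frame == "fwd" else "-",
        )
        if best is None or aln.edit_distance < best.edit_distance:
            best = aln
    return best


def _paired_rank(
    c1s: list[CandidateRegion], c2s: list[CandidateRegion], qp: QueryParams
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Re-rank each mate's candidates by paired-end accumulated score."""
    pairs = pair_candidates(c1s, c2s, qp)
    best1: dict[int, int] = {}
    best2: dict[int, int] = {}
    idx1 = {id(c): i for i, c in enumerate(c1s)}
    idx2 = {id(c): i for i, c in enumerate(c2s)}
    for p1, p2, score in pairs:
        if p1 is not None:
            i = idx1[id(p1)]
            best1[i] = max(best1.get(i, 0), score)
        if p2 is not None:
            j = idx2[id(p2)]
            best2[j] = max(best2.get(j, 0), score)

    def rank(cands, best):
        order = sorted(
            range(len(cands)),
            key=lambda i: (-best.get(i, 0), cands[i].target_id, cands[i].gstart, cands[i].strand),
        )
        return [cands[i] for i in order[: qp.max_candidates_per_read]]

    return rank(c1s, best1), rank(c2s, best2)


def collect_alignments(
    index: ReferenceIndex,
    reads: list,
    qp: QueryParams | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    batch_size: int = 100_000,
) -> AlignmentSet:
    """Stages 1–3: query, align and bucket every read by candidate region.

    ``reads`` are (read_id, mate, seq) triples; paired mates share a
    read_id and appear as mate 1 and 2.  Region buckets are keyed by
    (target, window-of-start) so that reads starting in the same reference
    window share one MSA later.
    """
    qp = qp or QueryParams()
    stride = index.params.stride
    # group input into fragments (read_id order preserved)
    frags: dict[str, list] = {}
    order: list[str] = []
    for r in reads:
        rid, mate, seq = r[0], r[1], r[2]
        if rid not in frags:
            frags[rid] = []
            order.append(rid)
        frags[rid].append((mate, seq))

    groups: dict[tuple[int, int], list[AlignedRead]] = {}
    read_keys: list[tuple[str, int]] = []
    read_seqs: dict[tuple[str, int], str] = {}
    n_cand = n_aln = 0

    for b0 in range(0, len(order), max(1, batch_size)):
        for rid in order[b0 : b0 + max(1, batch_size)]:
            mates = frags[rid]
            cands = [find_candidates(seq, index, qp) for _, seq in mates]
            if len(mates) == 2:
                cands = list(_paired_rank(cands[0], cands[1], qp))
            for (mate, seq), clist in zip(mates, cands):
                key = (rid, mate)
                read_keys.append(key)
                read_seqs[key] = seq
                n_cand += len(clist)
                max_dist = int((1.0 - min_score) * len(seq))
                seen: set[tuple[int, int, str]] = set()
                for c in clist:
                    aln = _align_candidate(seq, c, index, max_dist)
                    if aln is None:
                        continue
                    sig = (aln.target_id, aln.gstart, aln.strand)
                    if sig in seen:
                        continue
                    seen.add(sig)
                    n_aln += 1
                    aln = AlignedRead(
                        read_id=rid, mate=mate, seq=seq, strand=aln.strand,
                        target_id=aln.target_id, gstart=aln.gstart, gend=aln.gend,
                        cigar=aln.cigar, score=aln.score,
                        edit_distance=aln.edit_distance, conv_strand=aln.conv_strand,
                    )
                    gkey = (aln.target_id, aln.gstart // stride)
                    groups.setdefault(gkey, []).append(aln)
    return AlignmentSet(groups, read_keys, read_seqs, n_cand, n_aln)


def finalize_mappings(
    index: ReferenceIndex,
    alns: AlignmentSet,
    model: ForestModel | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    consensus_threshold: float = 0.8,
    collect_features: bool = False,
) -> MappingResult:
    """Stages 4–5: per-region MSA filtering and record assembly."""
    scheme = index.scheme
    kept: dict[tuple[str, int], list[MappingRecord]] = {}
    features: list[tuple] | None = [] if collect_features else None
    n_discarded = 0

    # First pass: build MSAs; batch every forest input across regions so the
    # ensemble is evaluated once (per-region calls would dominate runtime).
    prepared = []
    rf_X: list[np.ndarray] = []
    rf_slices: list[tuple[int, int]] = []
    for gkey in sorted(alns.groups):
        mappings = alns.groups[gkey]
        tid = gkey[0]
        ref = index.target_seqs[tid]
        region_start = min(m.gstart for m in mappings)
        region_end = max(m.gend for m in mappings)
        region = ref[region_start:region_end]
        in_msa = sorted(mappings, key=lambda m: (-m.score, m.read_id, m.mate))
        msa_rows, overflow = in_msa[:MAX_MSA_READS], in_msa[MAX_MSA_READS:]
        msa = build_msa(region, region_start, msa_rows)
        needs_rf = model is not None and msa.n_reads > 1
        if needs_rf or (collect_features and msa.n_reads > 1):
            prof = MSAProfile(msa, consensus_threshold)
            g = global_stats(msa)
            vecs = [
                feature_vector(msa, i, scheme, consensus_threshold, profile=prof, gstats=g)
                for i in range(msa.n_reads)
            ]
        else:
            vecs = None
        if needs_rf:
            rf_slices.append((len(rf_X), len(rf_X) + msa.n_reads))
            rf_X.extend(vecs)
        else:
            rf_slices.append((-1, -1))
        prepared.append((msa, overflow, vecs))
        if collect_features and msa.n_reads > 1:
            for i, m in enumerate(msa.reads):
                features.append(
                    (m.read_id, m.mate, m.target_id, m.gstart, m.gend, m.strand, vecs[i])
                )

    probs = (
        rf_classify_many(model, np.stack(rf_X)) if model is not None and rf_X else None
    )

    for (msa, overflow, _), (lo, hi) in zip(prepared, rf_slices):
        tid = msa.reads[0].target_id if msa.n_reads else None
        ref = index.target_seqs[tid] if tid is not None else ""
        if lo >= 0:
            decisions = [
                (float(p) >= model.decision_threshold, float(p)) for p in probs[lo:hi]
            ]
        else:
            decisions = filter_region(
                msa, model, min_score=min_score, scheme=scheme,
                consensus_threshold=consensus_threshold,
            )
        for i, (keep, p_pos) in enumerate(decisions):
            m = msa.reads[i]
            if not keep:
                n_discarded += 1
                continue
            rec = MappingRecord(
                read_id=m.read_id, mate=m.mate, target_id=m.target_id,
                gstart=m.gstart, gend=m.gend, strand=m.strand, cigar=m.cigar,
                score=m.score, edit_distance=m.edit_distance,
                n_conversions=count_conversions(msa, i, scheme),
                conv_positions=conversion_positions(msa, i, scheme),
                p_positive=p_pos, seq=m.seq,
            )
            kept.setdefault((m.read_id, m.mate), []).append(rec)
        # reads beyond the 16-row MSA cap fall back to the score-only rule
        for m in overflow:
            if m.score < min_score:
                n_discarded += 1
                continue
            sub = build_msa(ref[m.gstart : m.gend], m.gstart, [m])
            rec = MappingRecord(
                read_id=m.read_id, mate=m.mate, target_id=m.target_id,
                gstart=m.gstart, gend=m.gend, strand=m.strand, cigar=m.cigar,
                score=m.score, edit_distance=m.edit_distance,
                n_conversions=count_conversions(sub, 0, scheme),
                conv_positions=conversion_positions(sub, 0, scheme),
                seq=m.seq,
            )
            kept.setdefault((m.read_id, m.mate), []).append(rec)

    records: list[MappingRecord] = []
    n_mapped = 0
    for key in alns.read_keys:
        recs = kept.get(key, [])
        if not recs:
            records.append(
                MappingRecord(
                    read_id=key[0], mate=key[1], target_id=-1, gstart=-1, gend=-1,
                    strand=".", cigar="", score=0.0, edit_distance=-1,
                    n_conversions=0, seq=alns.read_seqs[key],
                )
            )
            continue
        n_mapped += 1
        recs.sort(
            key=lambda r: (
                -(r.p_positive if r.p_positive is not None else 1.0),
                -r.score, r.target_id, r.gstart, r.strand,
            )
        )
        for j, r in enumerate(recs):
            r.is_primary = j == 0
            r.multiplicity = len(recs)
        records.extend(recs)
    report = {
        "n_reads": len(alns.read_keys),
        "n_candidates": alns.n_candidates,
        "n_alignments": alns.n_alignments,
        "n_mapped": n_mapped,
        "n_discarded_by_filter": n_discarded,
    }
    return MappingResult(records, report, features)


def map_reads(
    index: ReferenceIndex,
    reads: list,
    qp: QueryParams | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    model: ForestModel | None = None,
    consensus_threshold: float = 0.8,
    batch_size: int = 100_000,
    collect_features: bool = False,
) -> MappingResult:
    """Run the full pipeline over (read_id, mate, seq) triples."""
    alns = collect_alignments(index, reads, qp, min_score, batch_size)
    return finalize_mappings(index, alns, model, min_score, consensus_threshold, collect_features)


def train_filter(
    index: ReferenceIndex,
    reads: list,
    truth,
    qp: QueryParams | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    min_overlap: float = 0.9,
    n_trees: int = 100,
    max_depth: int = 12,
    seed: int = 0,
) -> ForestModel:
    """Train the mapping filter from simulated reads with known truth.

    The unfiltered pipeline is run to produce feature vectors for every
    mapping in a multi-read region; a mapping is labelled positive when its
    span overlaps the read's true origin by at least ``min_overlap`` of the
    read length on the correct target and strand.
    """
    from .msa import rf_train

    result = map_reads(index, reads, qp, min_score, model=None, collect_features=True)
    tkey = {}
    for row in truth.itertuples():
        tkey[(row.read_id, row.mate)] = (row.target_id, row.start, row.end, row.strand)
    X, y = [], []
    for rid, mate, tid, gs, ge, strand, vec in result.features:
        true_tid, ts, te, tstrand = tkey[(rid, mate)]
        need = min_overlap * (te - ts)
        ok = tid == true_tid and strand == tstrand and min(ge, te) - max(gs, ts) >= need
        X.append(vec)
        y.append(1 if ok else 0)
    return rf_train(np.array(X), np.array(y), n_trees=n_trees, max_depth=max_depth, seed=seed)
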