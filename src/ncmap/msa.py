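"""Region MSAs, column/read/global statistics, and the mapping filter.

After alignment, reads mapped to a common reference region are stacked —
in the ORIGINAL four-letter alphabet — into a small multiple sequence
alignment (at most 16 read rows) together with the original reference
subsequence.  Column statistics (nucleotide composition, most common
nucleotide, consensus), per-read statistics (alignment score, deviation
from reference and from consensus) and global statistics (read count,
min/avg/max score) summarise the region.  These feed a random-forest
classifier that separates genuine mappings from false positives; a read
that shares a region with nothing else is filtered only by a minimum
alignment-score threshold.

The key point of working in the original alphabet is that expected
chemical conversions (e.g. C→T for bisulfite) can be told apart from
sequencing errors: conversion-consistent mismatches are excluded from the
deviation statistics and counted separately as conversions.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .seqcore import ConversionScheme, reverse_complement

__all__ = [
    "AlignedRead",
    "MSA",
    "ColumnStats",
    "ReadStats",
    "MSAGlobalStats",
    "ForestModel",
    "build_msa",
    "column_stats",
    "read_stats",
    "global_stats",
    "count_conversions",
    "conversion_positions",
    "feature_vector",
    "FEATURE_NAMES",
    "rf_train",
    "rf_classify",
    "filter_region",
    "save_model",
    "load_model",
]

MAX_MSA_READS = 16
DEFAULT_CONSENSUS_THRESHOLD = 0.8

GAP = "-"
PAD = " "

_MODEL_FORMAT_VERSION = 1

FEATURE_NAMES = [
    "align_score",
    "pct_dev_ref",
    "pct_dev_consensus",
    "n_reads",
    "min_score",
    "avg_score",
    "max_score",
    "frac_m_agrees_ref",
    "frac_consensus_defined",
]


@dataclass(frozen=True)
class AlignedRead:
    """One read-to-region mapping, in forward reference frame.

    ``seq`` is the read as sequenced (original alphabet); for '−'-strand
    mappings its reverse complement is what occupies the MSA row.  ``cigar``
    is forward-frame (=/X/I/D), ``gstart`` the 0-based genomic start.
    """

    read_id: str
    mate: int
    seq: str
    strand: str
    target_id: int
    gstart: int
    gend: int
    cigar: str
    score: float
    edit_distance: int
    # strand on which the chemistry acted, in forward-reference frame: '+'
    # means the conversion appears as (from_base → to_base) in forward
    # coordinates, '-' as the complementary pair.  For paired data this is a
    # property of the fragment, not of the mapping strand (mate 2 of a
    # forward fragment maps '-' yet still shows the scheme pair).
    conv_strand: str = "+"


@dataclass
class MSA:
    """Reference row plus ≤16 read rows, all equal length.

    ``ref_positions[col]`` is the genomic position of a reference column or
    −1 for insertion columns.  Read rows use '-' for deletions/absent
    insertions and ' ' for leading/trailing pad outside the read.
    """

    region_row: str
    rows: list[str]
    reads: list[AlignedRead]
    ref_positions: np.ndarray
    _arr: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cols(self) -> int:
        return len(self.region_row)

    @property
    def n_reads(self) -> int:
        return len(self.rows)

    def as_array(self) -> np.ndarray:
        if self._arr is None:
            self._arr = np.array(
                [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in self.rows],
                dtype=np.uint8,
            ).reshape(len(self.rows), -1)
        return self._arr


@dataclass(frozen=True)
class ColumnStats:
    coverage: int
    frac_a: float
    frac_c: float
    frac_g: float
    frac_t: float
    most_common: str | None
    m_agrees_ref: bool
    consensus: str | None


@dataclass(frozen=True)
class ReadStats:
    align_score: float
    pct_dev_ref: float
    pct_dev_consensus: float


@dataclass(frozen=True)
class MSAGlobalStats:
    n_reads: int
    min_score: float
    avg_score: float
    max_score: float


# ---------------------------------------------------------------------------
# MSA construction


def _cigar_walk(cigar: str):
    import re

    for m in re.finditer(r"(\d+)([=XIDM])", cigar):
        yield int(m.group(1)), m.group(2)


def build_msa(
    region_original: str,
    region_offset: int,
    mappings: list[AlignedRead],
    max_rows: int = MAX_MSA_READS,
) -> MSA:
    """Stack mapped reads over the original reference subsequence.

    Reads are shifted according to their alignments; insertion columns are
    added to the reference row ('-') wherever any read inserts, with one
    shared block per reference position sized by the longest insertion
    there.  If more than ``max_rows`` reads map, the highest-scoring are
    kept (ties broken by read id, then mate).
    """
    mappings = sorted(mappings, key=lambda m: (-m.score, m.read_id, m.mate))[:max_rows]
    L = len(region_original)

    # insertion block width needed before each reference offset (0..L)
    ins_before: dict[int, int] = {}
    walks = []
    for m in mappings:
        off = m.gstart - region_offset
        if off < 0 or m.gend - region_offset > L:
            raise ValueError("mapping lies outside the provided region")
        ops = list(_cigar_walk(m.cigar))
        qlen = sum(n for n, op in ops if op in "=XMI")
        if qlen != len(m.seq):
            raise ValueError(
                f"CIGAR consumes {qlen} query bases but read {m.read_id} has {len(m.seq)}"
            )
        walks.append((m, off, ops))
        pos = off
        for n, op in ops:
            if op == "I":
                ins_before[pos] = max(ins_before.get(pos, 0), n)
            elif op in "=XMD":
                pos += n

    if not ins_before:
        # fast path: no insertion columns, layout is the reference itself
        rows = []
        for m, off, ops in walks:
            row = bytearray(b" " * L)
            rseq = (m.seq if m.strand == "+" else reverse_complement(m.seq)).encode("ascii")
            qi, pos = 0, off
            for n, op in ops:
                if op in "=XM":
                    row[pos : pos + n] = rseq[qi : qi + n]
                    qi += n
                    pos += n
                elif op == "D":
                    row[pos : pos + n] = b"-" * n
                    pos += n
            rows.append(row.decode("ascii"))
        return MSA(
            region_original, rows, mappings,
            np.arange(region_offset, region_offset + L, dtype=np.int64),
        )

    # column layout
    col_of_ref = np.zeros(L + 1, dtype=np.int64)
    ref_positions = []
    col = 0
    for pos in range(L + 1):
        col += ins_before.get(pos, 0)
        col_of_ref[pos] = col
        if pos < L:
            ref_positions.append(region_offset + pos)
            col += 1
    n_cols = col
    ref_pos_arr = np.full(n_cols, -1, dtype=np.int64)
    for pos in range(L):
        ref_pos_arr[col_of_ref[pos]] = region_offset + pos

    region_row = [GAP] * n_cols
    for pos in range(L):
        region_row[col_of_ref[pos]] = region_original[pos]

    rows = []
    for m, off, ops in walks:
        row = [PAD] * n_cols
        rseq = m.seq if m.strand == "+" else reverse_complement(m.seq)
        qi = 0
        pos = off
        for n, op in ops:
            if op in "=XM":
                for j in range(n):
                    row[col_of_ref[pos + j]] = rseq[qi + j]
                qi += n
                pos += n
            elif op == "D":
                for j in range(n):
                    row[col_of_ref[pos + j]] = GAP
                pos += n
            elif op == "I":
                block = col_of_ref[pos] - ins_before.get(pos, 0)
                for j in range(n):
                    row[block + j] = rseq[qi + j]
                for j in range(n, ins_before.get(pos, 0)):
                    row[block + j] = GAP
                qi += n
        # internal insertion blocks the read spans but does not use → gap
        first = col_of_ref[off]
        last = col_of_ref[pos - 1] if pos > off else first
        for c in range(first, last + 1):
            if row[c] == PAD:
                row[c] = GAP
        rows.append("".join(row))

    return MSA("".join(region_row), rows, mappings, ref_pos_arr)


# ---------------------------------------------------------------------------
# statistics

_BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP_CODE = ord(GAP)
_PAD_CODE = ord(PAD)


class MSAProfile:
    """Vectorised per-column statistics for one MSA."""

    def __init__(self, msa: MSA, consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD):
        self.msa = msa
        self.consensus_threshold = consensus_threshold
        arr = msa.as_array()
        ref = np.frombuffer(msa.region_row.encode("ascii"), dtype=np.uint8)
        self.ref = ref
        counts = np.zeros((4, msa.n_cols), dtype=np.int64)
        for bi, bc in enumerate(_BASE_CODES):
            counts[bi] = (arr == bc).sum(axis=0)
        self.counts = counts
        self.coverage = counts.sum(axis=0)
        # most common nucleotide; ties → the base matching the reference,
        # else alphabetical (argmax picks the first=alphabetical maximum)
        maxc = counts.max(axis=0)
        self.m_idx = counts.argmax(axis=0)
        for bi, bc in enumerate(_BASE_CODES):
            tie_ref = (counts[bi] == maxc) & (ref == bc) & (maxc > 0)
            self.m_idx[tie_ref] = bi
        self.has_m = self.coverage > 0
        self.m_code = np.where(self.has_m, _BASE_CODES[self.m_idx], 0).astype(np.uint8)
        self.m_agrees = self.has_m & (self.m_code == ref)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(self.coverage > 0, maxc / np.maximum(self.coverage, 1), 0.0)
        self.has_consensus = self.has_m & (rel >= consensus_threshold)
        self.consensus_code = np.where(self.has_consensus, self.m_code, 0).astype(np.uint8)


def column_stats(
    msa: MSA, col: int, consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD
) -> ColumnStats:
    """Composition, most common nucleotide and consensus of one column."""
    if not (0 <= col < msa.n_cols):
        raise IndexError(f"column {col} out of range")
    prof = MSAProfile(msa, consensus_threshold)
    cov = int(prof.coverage[col])
    fracs = [100.0 * prof.counts[bi, col] / cov if cov else 0.0 for bi in range(4)]
    return ColumnStats(
        coverage=cov,
        frac_a=fracs[0],
        frac_c=fracs[1],
        frac_g=fracs[2],
        frac_t=fracs[3],
        most_common=chr(prof.m_code[col]) if prof.has_m[col] else None,
        m_agrees_ref=bool(prof.m_agrees[col]),
        consensus=chr(prof.consensus_code[col]) if prof.has_consensus[col] else None,
    )


def _conversion_codes(scheme: ConversionScheme, conv_strand: str) -> tuple[int, int]:
    fb, tb = (scheme.from_base, scheme.to_base) if conv_strand == "+" else scheme.complement_pair
    return ord(fb), ord(tb)


def _row_masks(msa: MSA, row: int):
    arr = msa.as_array()
    r = arr[row]
    nongap = (r != _GAP_CODE) & (r != _PAD_CODE)
    return r, nongap


def read_stats(
    msa: MSA,
    row: int,
    scheme: ConversionScheme,
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
    conversions_are_deviations: bool = False,
    profile: MSAProfile | None = None,
) -> ReadStats:
    """Per-read deviation statistics over its non-gap columns.

    A read-vs-reference difference that matches the expected chemical
    conversion (reference from-base over read to-base, strand-adjusted) is
    not counted as a deviation unless ``conversions_are_deviations`` is
    set.  Deviation from consensus is measured only over columns where a
    consensus is defined (0 if there are none).
    """
    prof = profile or MSAProfile(msa, consensus_threshold)
    r, nongap = _row_masks(msa, row)
    ref = prof.ref
    fb, tb = _conversion_codes(scheme, msa.reads[row].conv_strand)
    dev = nongap & (r != ref)
    if not conversions_are_deviations:
        dev &= ~((ref == fb) & (r == tb))
    n = int(nongap.sum())
    pct_dev_ref = 100.0 * dev.sum() / n if n else 0.0
    cons_cols = nongap & prof.has_consensus
    nc = int(cons_cols.sum())
    dev_cons = cons_cols & (r != prof.consensus_code)
    if not conversions_are_deviations:
        dev_cons &= ~((prof.consensus_code == fb) & (r == tb))
    pct_dev_cons = 100.0 * dev_cons.sum() / nc if nc else 0.0
    return ReadStats(msa.reads[row].score, float(pct_dev_ref), float(pct_dev_cons))


def global_stats(msa: MSA) -> MSAGlobalStats:
    """Read count and min/avg/max alignment score of the region."""
    if msa.n_reads == 0:
        raise ValueError("empty MSA")
    scores = [m.score for m in msa.reads]
    return MSAGlobalStats(
        len(scores), min(scores), float(sum(scores) / len(scores)), max(scores)
    )


def _conversion_mask(msa: MSA, row: int, scheme: ConversionScheme) -> np.ndarray:
    r, nongap = _row_masks(msa, row)
    ref = np.frombuffer(msa.region_row.encode("ascii"), dtype=np.uint8)
    fb, tb = _conversion_codes(scheme, msa.reads[row].conv_strand)
    return nongap & (ref == fb) & (r == tb)


def count_conversions(msa: MSA, row: int, scheme: ConversionScheme) -> int:
    """Columns where the reference shows the from-base and the read the
    to-base (complement pair for '−'-strand rows)."""
    return int(_conversion_mask(msa, row, scheme).sum())


def conversion_positions(msa: MSA, row: int, scheme: ConversionScheme) -> list[int]:
    """Genomic positions (0-based) of the identified conversions."""
    mask = _conversion_mask(msa, row, scheme)
    return [int(p) for p in msa.ref_positions[mask] if p >= 0]


def feature_vector(
    msa: MSA,
    row: int,
    scheme: ConversionScheme,
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
    profile: MSAProfile | None = None,
    gstats: MSAGlobalStats | None = None,
) -> np.ndarray:
    """The classifier input for one mapping; ordering per FEATURE_NAMES."""
    prof = profile or MSAProfile(msa, consensus_threshold)
    g = gstats or global_stats(msa)
    rs = read_stats(msa, row, scheme, consensus_threshold, profile=prof)
    _, nongap = _row_masks(msa, row)
    n = int(nongap.sum())
    frac_agree = float((nongap & prof.m_agrees).sum() / n) if n else 0.0
    frac_cons = float((nongap & prof.has_consensus).sum() / n) if n else 0.0
    return np.array(
        [
            rs.align_score,
            rs.pct_dev_ref,
            rs.pct_dev_consensus,
            g.n_reads,
            g.min_score,
            g.avg_score,
            g.max_score,
            frac_agree,
            frac_cons,
        ],
        dtype=np.float64,
    )


# ---------------------------------------------------------------------------
# random-forest filter


@dataclass
class ForestModel:
    """A trained mapping filter: sklearn forest plus decision threshold.

    Each tree votes with its leaf class probabilities; the ensemble
    probability is their mean and a mapping is kept when the positive-class
    probability is >= ``decision_threshold`` (boundary keeps).
    """

    forest: RandomForestClassifier
    feature_names: list[str]
    n_trees: int
    max_depth: int
    seed: int
    decision_threshold: float = 0.5
    format_version: int = _MODEL_FORMAT_VERSION


def rf_train(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    max_depth: int = 12,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> ForestModel:
    """Train the mapping filter on labelled feature vectors.

    Standard random forest: bootstrap resampling per tree, √d feature
    subsampling at each split, Gini impurity.  Labels are 1 for a true
    mapping and 0 for a false one; both classes must be present.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected feature matrix with {len(FEATURE_NAMES)} columns")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ForestModel(forest, list(FEATURE_NAMES), n_trees, max_depth, seed, decision_threshold)


def _positive_index(model: ForestModel) -> int:
    return int(np.flatnonzero(model.forest.classes_ == 1)[0])


def rf_classify(model: ForestModel, x: np.ndarray) -> tuple[float, bool]:
    """Ensemble positive probability (mean over trees) and keep decision."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (len(model.feature_names),):
        raise ValueError(
            f"feature vector has shape {x.shape}, model expects ({len(model.feature_names)},)"
        )
    p = float(model.forest.predict_proba(x.reshape(1, -1))[0, _positive_index(model)])
    return p, p >= model.decision_threshold


def rf_classify_many(model: ForestModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return model.forest.predict_proba(X)[:, _positive_index(model)]


def filter_region(
    msa: MSA,
    model: ForestModel | None,
    min_score: float = 0.8,
    scheme: ConversionScheme | None = None,
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> list[tuple[bool, float | None]]:
    """Keep/discard decision (and filter probability) for every MSA row.

    A region with a single read is filtered only by the minimum
    alignment-score threshold; with the filter disabled (``model`` None)
    the same score rule applies to every read.  Otherwise each read is
    classified by the random forest on its feature vector.
    """
    if msa.n_reads == 0:
        return []
    if model is None or msa.n_reads == 1:
        return [(m.score >= min_score, None) for m in msa.reads]
    if scheme is None:
        raise ValueError("scheme required for feature computation")
    prof = MSAProfile(msa, consensus_threshold)
    g = global_stats(msa)
    X = np.stack(
        [
            feature_vector(msa, i, scheme, consensus_threshold, profile=prof, gstats=g)
            for i in range(msa.n_reads)
        ]
    )
    probs = rf_classify_many(model, X)
    return [(float(p) >= model.decision_threshold, float(p)) for p in probs]


def save_model(model: ForestModel, path: str) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh, protocol=4)


def load_model(path: str) -> ForestModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, ForestModel) or model.format_version != _MODEL_FORMAT_VERSION:
        raise ValueError("not a compatible filter model file")
    return model
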