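"""Synthetic 3N sequencing data with ground truth.

Emulates the two simulation regimes commonly used to benchmark
conversion-aware mappers: paired-end whole-genome bisulfite reads (50%
C→T conversion per cytosine, 0.2% per-base substitution error) and
single-end SLAM-seq reads drawn from 3′ transcript regions (2% T→C
conversion).  Fragments are sampled uniformly (or 3′-windowed), a strand
is chosen uniformly, conversions are applied to each convertible base of
the originating strand, then independent substitution errors.  Every read
carries a truth record (origin span, strand, planted conversion and error
counts) so that mapping output can be scored exactly.

Synthetic genomes optionally contain repeat families — segments copied to
several locations with a per-copy divergence — because repeats are what
make real mapping hard: they produce multi-mapped reads and the
false-positive mappings the downstream filter is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .seqcore import ConversionScheme, reverse_complement

__all__ = [
    "SimParams",
    "SimRead",
    "random_genome",
    "simulate_reads",
    "evaluate_mappings",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimRead(NamedTuple):
    read_id: str
    mate: int  # 0 = single-end, 1/2 = paired mates
    seq: str


@dataclass(frozen=True)
class SimParams:
    """Simulation settings; defaults follow common benchmark conditions."""

    n_fragments: int = 1000
    read_len: int = 100
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 25.0
    conv_rate: float = 0.5
    err_rate: float = 0.002
    scheme: ConversionScheme = ConversionScheme("C", "T")
    three_prime_bias: bool = False
    three_prime_window: int = 250
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.conv_rate <= 1 and 0 <= self.err_rate <= 1):
            raise ValueError("conv_rate and err_rate must lie in [0, 1]")

    @classmethod
    def bs_seq(cls, n_fragments: int, seed: int, **kw) -> "SimParams":
        """Paired-end bisulfite regime: 50% C→T, 0.2% error, 100 bp."""
        kw.setdefault("paired", True)
        kw.setdefault("conv_rate", 0.5)
        kw.setdefault("err_rate", 0.002)
        kw.setdefault("scheme", ConversionScheme("C", "T"))
        return cls(n_fragments=n_fragments, seed=seed, **kw)

    @classmethod
    def slam_seq(cls, n_fragments: int, seed: int, **kw) -> "SimParams":
        """Single-end SLAM regime: 2% T→C, 0.2% error, 3′-biased sampling."""
        kw.setdefault("conv_rate", 0.02)
        kw.setdefault("err_rate", 0.002)
        kw.setdefault("scheme", ConversionScheme("T", "C"))
        kw.setdefault("three_prime_bias", True)
        return cls(n_fragments=n_fragments, seed=seed, **kw)


def random_genome(
    length: int,
    seed: int,
    gc: float = 0.41,
    n_contigs: int = 1,
    repeat_fraction: float = 0.05,
    repeat_length: tuple[int, int] = (300, 2000),
    copy_number: tuple[int, int] = (2, 4),
    divergence: tuple[float, float] = (0.0, 0.05),
    name_prefix: str = "chr",
) -> list[tuple[str, str]]:
    """A synthetic genome with interspersed repeat families.

    ``repeat_fraction`` of the sequence is covered by copies of randomly
    chosen source segments; each copy is substituted at a per-base rate
    drawn uniformly from ``divergence``, mimicking repeat families of mixed
    age (young near-identical copies through diverged older ones).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = []
    per = length // n_contigs
    for ci in range(n_contigs):
        codes = rng.choice(4, size=per, p=p).astype(np.uint8)
        pasted = 0
        while pasted < repeat_fraction * per:
            rl = int(rng.integers(repeat_length[0], repeat_length[1] + 1))
            if rl >= per // 2:
                break
            src = int(rng.integers(0, per - rl))
            unit = codes[src : src + rl].copy()
            for _ in range(int(rng.integers(copy_number[0], copy_number[1] + 1)) - 1):
                d = rng.uniform(*divergence)
                copy = unit.copy()
                mut = rng.random(rl) < d
                copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
                dst = int(rng.integers(0, per - rl))
                codes[dst : dst + rl] = copy
                pasted += rl
        contigs.append((f"{name_prefix}{ci + 1}", _BASES[codes].tobytes().decode()))
    return contigs


def _apply_conversions(frag: np.ndarray, fb: int, tb: int, rate: float, rng) -> np.ndarray:
    sites = np.flatnonzero(frag == fb)
    hit = sites[rng.random(len(sites)) < rate]
    frag[hit] = tb
    return hit


def _apply_errors(frag: np.ndarray, rate: float, rng) -> np.ndarray:
    hit = np.flatnonzero(rng.random(len(frag)) < rate)
    frag[hit] = (frag[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return hit


_CODE = {b: i for i, b in enumerate("ACGT")}


def simulate_reads(
    references: Sequence[tuple[str, str]], p: SimParams
) -> tuple[list[SimRead], pd.DataFrame]:
    """Generate reads and their truth table.

    Fragments are sampled uniformly per base across references (restricted
    to a 3′ window when ``three_prime_bias`` is set), oriented on a
    uniformly chosen strand, converted at ``conv_rate`` per convertible
    base, then hit by substitution errors at ``err_rate`` per base.  Paired
    mode emits proper forward–reverse pairs with insert length
    ~Normal(insert_mean, insert_sd), truncated to at least ``read_len``.
    Deterministic given ``p.seed``.
    """
    rng = np.random.default_rng(p.seed)
    rl = p.read_len
    enc = []
    for name, seq in references:
        if len(seq) < rl:
            raise ValueError(f"reference {name} shorter than read length {rl}")
        enc.append(np.array([_CODE.get(c.upper(), 0) for c in seq], dtype=np.uint8))
    lens = np.array([len(e) for e in enc], dtype=np.float64)
    tprob = lens / lens.sum()
    fb, tb = _CODE[p.scheme.from_base], _CODE[p.scheme.to_base]

    reads: list[SimRead] = []
    truth_rows = []
    for i in range(p.n_fragments):
        tid = int(rng.choice(len(enc), p=tprob))
        ref = enc[tid]
        L = len(ref)
        if p.paired:
            flen = int(round(rng.normal(p.insert_mean, p.insert_sd)))
            flen = max(rl, min(flen, L))
        else:
            flen = rl
        if p.three_prime_bias:
            lo = max(0, L - p.three_prime_window - flen)
            start = int(rng.integers(lo, L - flen + 1))
        else:
            start = int(rng.integers(0, L - flen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = ref[start : start + flen].copy()
        if strand == "-":
            frag = (3 - frag)[::-1]  # reverse complement in code space
        conv_idx = _apply_conversions(frag, fb, tb, p.conv_rate, rng)
        err_idx = _apply_errors(frag, p.err_rate, rng)
        rid = f"r{i:07d}"
        mates = [(1, frag[:rl]), (2, (3 - frag[flen - rl :])[::-1])] if p.paired else [(0, frag)]
        for mate, mseq in mates:
            # fragment-frame interval occupied by this mate
            flo, fhi = (0, rl) if mate in (0, 1) else (flen - rl, flen)
            nconv = int(((conv_idx >= flo) & (conv_idx < fhi)).sum())
            nerr = int(((err_idx >= flo) & (err_idx < fhi)).sum())
            # genomic coordinates and mapping strand of this mate
            if strand == "+":
                gs, ge = start + flo, start + fhi
                mstrand = "+" if mate in (0, 1) else "-"
            else:
                gs, ge = start + flen - fhi, start + flen - flo
                mstrand = "-" if mate in (0, 1) else "+"
            reads.append(SimRead(rid, mate, _BASES[mseq].tobytes().decode()))
            truth_rows.append((rid, mate, tid, gs, ge, mstrand, nconv, nerr))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "mate", "target_id", "start", "end",
            "strand", "n_conversions", "n_errors",
        ],
    )
    return reads, truth


def write_fastq(reads: Sequence[SimRead], path: str, mate: int | None = None) -> None:
    """Plain FASTQ with uniform quality; filter to one mate if requested."""
    with open(path, "w") as fh:
        for r in reads:
            if mate is not None and r.mate != mate:
                continue
            suffix = f"/{r.mate}" if r.mate else ""
            fh.write(f"@{r.read_id}{suffix}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# evaluation


def evaluate_mappings(
    records: Sequence, truth: pd.DataFrame, min_overlap: float = 0.9
) -> dict:
    """Score mapping output against the truth table.

    A reported location is *correct* when it lies on the true target and
    strand and overlaps the true origin by at least ``min_overlap`` of the
    read length.  A multi-mapped read counts as correctly aligned if any of
    its locations is correct; unique metrics consider only reads with a
    single reported location.  Rates are percentages of all simulated
    reads; ``fp_count`` is the number of kept mappings that are not
    correct.

    ``records`` are mapping records with attributes read_id, mate,
    target_id, gstart, gend, strand and a truthy mapped state (unmapped
    records have target_id < 0).
    """
    tkey = {}
    for row in truth.itertuples():
        tkey[(row.read_id, row.mate)] = (row.target_id, row.start, row.end, row.strand)
    if not tkey:
        raise ValueError("empty truth table")

    by_read: dict[tuple[str, int], list] = {}
    for r in records:
        if getattr(r, "target_id", -1) < 0:
            continue
        if (r.read_id, r.mate) not in tkey:
            raise KeyError(f"read {r.read_id}/{r.mate} not present in truth table")
        by_read.setdefault((r.read_id, r.mate), []).append(r)

    n_total = len(tkey)
    n_mapped = n_unique = n_correct = n_unique_correct = fp = 0
    for key, locs in by_read.items():
        tid, ts, te, tstrand = tkey[key]
        rlen = te - ts
        need = min_overlap * rlen
        n_mapped += 1
        oks = []
        for r in locs:
            ok = (
                r.target_id == tid
                and r.strand == tstrand
                and min(r.gend, te) - max(r.gstart, ts) >= need
            )
            oks.append(ok)
            if not ok:
                fp += 1
        if any(oks):
            n_correct += 1
        if len(locs) == 1:
            n_unique += 1
            if oks[0]:
                n_unique_correct += 1
    pct = lambda x: 100.0 * x / n_total
    return {
        "n_reads": n_total,
        "align_rate": pct(n_mapped),
        "unique_align_rate": pct(n_unique),
        "accuracy": pct(n_correct),
        "unique_accuracy": pct(n_unique_correct),
        "fp_count": fp,
    }
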