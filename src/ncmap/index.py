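"""MinHash-sketched 3N reference index.

The reference is converted to the reduced three-letter alphabet and split
into overlapping windows (default 64 bp, overlapping by k−1 so that every
k-mer belongs to exactly one window).  Each window is summarised by a
bottom-s MinHash sketch of its k-mer hashes; the sketch overlap between a
read window and a reference window estimates their k-mer Jaccard
similarity.  Sketched features are stored in a hash table mapping a feature
to the ascending list of (target, window) locations that contain it.

Two such tables are built: one from the converted forward reference and one
from the converted reverse complement.  The conversion does not commute
with reverse complementation, so both orientations genuinely need their own
table.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .seqcore import ConversionScheme, convert_3n, encode, reverse_complement

__all__ = [
    "IndexParams",
    "Location",
    "FeatureTable",
    "ReferenceIndex",
    "windows",
    "sketch",
    "kmer_hashes",
    "build_index",
    "lookup",
    "save_index",
    "load_index",
]

_INDEX_FORMAT_VERSION = 1

_U64 = np.uint64
_SPLITMIX_C1 = _U64(0xBF58476D1CE4E5B9)
_SPLITMIX_C2 = _U64(0x94D049BB133111EB)
_SPLITMIX_INC = _U64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray | int) -> np.ndarray | np.uint64:
    """Well-mixing 64-bit finalizer (splitmix64), vectorised over uint64."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    z = np.asarray(x, dtype=_U64)
    with np.errstate(over="ignore"):
        z = z + _SPLITMIX_INC
        z = (z ^ (z >> _U64(30))) * _SPLITMIX_C1
        z = (z ^ (z >> _U64(27))) * _SPLITMIX_C2
        z = z ^ (z >> _U64(31))
    return z[()] if scalar else z


@dataclass(frozen=True)
class IndexParams:
    """Sketching parameters.

    w: window length in bp; k: k-mer length; s: sketch size (features kept
    per window); hash_seed: fixes both hash functions h1 (k-mer → feature)
    and h2 (feature → bucket key); max_locations_per_feature: features with
    more reference locations than this are treated as over-represented
    (repeat-derived) and ignored at query time; ``None`` disables the cap.
    """

    w: int = 64
    k: int = 16
    s: int = 16
    hash_seed: int = 42
    max_locations_per_feature: int | None = 256

    def __post_init__(self):
        if not (1 <= self.k <= self.w):
            raise ValueError(f"need 1 <= k <= w, got k={self.k}, w={self.w}")
        if self.k > 32:
            raise ValueError("k must be <= 32 (2-bit packed into 64 bits)")
        if self.s < 1:
            raise ValueError("sketch size s must be >= 1")

    @property
    def stride(self) -> int:
        return self.w - self.k + 1

    @property
    def h1_seed(self) -> np.uint64:
        return _splitmix64(np.uint64(self.hash_seed & 0xFFFFFFFFFFFFFFFF))

    @property
    def h2_seed(self) -> np.uint64:
        return _splitmix64(np.uint64((self.hash_seed ^ 0x5DEECE66D) & 0xFFFFFFFFFFFFFFFF))


class Location(NamedTuple):
    """A reference position at window resolution: (target_id, window_id)."""

    target_id: int
    window_id: int


def _pack(target_id: int, window_id: int) -> int:
    return (target_id << 32) | window_id


def _unpack(packed: int) -> Location:
    return Location(int(packed) >> 32, int(packed) & 0xFFFFFFFF)


def windows(seq: str, params: IndexParams) -> Iterator[tuple[int, int, str]]:
    """Yield (window_id, start_offset, window_seq) tiles of ``seq``.

    Windows of length ``w`` overlap by ``k−1`` bp (stride ``w−k+1``), so
    every k-mer of ``seq`` lies in exactly one window.  The final window may
    be shorter than ``w`` but is only emitted if at least one k-mer fits.
    Sequences shorter than ``k`` yield nothing.
    """
    L = len(seq)
    stride = params.stride
    wid = 0
    off = 0
    while off <= L - params.k:
        yield wid, off, seq[off : off + params.w]
        wid += 1
        off += stride


def kmer_hashes(seq_codes: np.ndarray, params: IndexParams) -> np.ndarray:
    """h1 values for every k-mer of an encoded sequence (N k-mers dropped).

    Returns one value per k-mer start position; positions whose k-mer
    contains N are removed.  Order follows sequence position.
    """
    k = params.k
    n = len(seq_codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64)
    valid = seq_codes != 4
    ok = np.ones(n, dtype=bool)
    for j in range(k):  # k short vector passes; no window view materialised
        ok &= valid[j : j + n]
    codes = np.where(valid, seq_codes, 0).astype(_U64)
    code = np.zeros(n, dtype=_U64)
    for j in range(k):  # Horner accumulation of the 2-bit packed k-mer
        code = (code << _U64(2)) | codes[j : j + n]
    return _splitmix64(code ^ params.h1_seed)[ok]


def _sketch_from_hashes(h1_values: np.ndarray, s: int) -> np.ndarray:
    """Bottom-s sketch: the s smallest *distinct* h1 values, ascending."""
    if len(h1_values) == 0:
        return h1_values
    return np.unique(h1_values)[:s]


def sketch(window_seq: str, params: IndexParams) -> list[int]:
    """Bottom-s MinHash sketch of a window: ascending distinct h1 values.

    K-mers containing N are skipped; a window with no valid k-mer yields an
    empty sketch.  If fewer than ``s`` distinct values exist, all are kept.
    """
    return [int(v) for v in _sketch_from_hashes(kmer_hashes(encode(window_seq), params), params.s)]


class FeatureTable:
    """Hash table mapping bucket key h2(feature) → sorted packed locations.

    Stored as three parallel arrays (sorted unique keys, per-key offsets,
    flat location array); lookups binary-search the key array.  Location
    lists are ascending in (target_id, window_id) and duplicate-free.
    Over-represented features (location list longer than
    ``max_locations_per_feature``) return no locations from lookups but
    remain stored.
    """

    def __init__(self, h2_seed: np.uint64, max_locations: int | None):
        self._h2_seed = _U64(h2_seed)
        self._max_locations = max_locations
        self._keys = np.empty(0, dtype=_U64)
        self._offsets = np.zeros(1, dtype=np.int64)
        self._flat = np.empty(0, dtype=_U64)

    def h2(self, features: np.ndarray) -> np.ndarray:
        return _splitmix64(np.asarray(features, dtype=_U64) ^ self._h2_seed)

    def _find(self, keys: np.ndarray) -> np.ndarray:
        """Indices into the key array, or −1 where absent/over-represented."""
        if len(self._keys) == 0:
            return np.full(len(keys), -1, dtype=np.int64)
        idx = np.minimum(np.searchsorted(self._keys, keys), len(self._keys) - 1)
        found = self._keys[idx] == keys
        counts = self._offsets[idx + 1] - self._offsets[idx]
        if self._max_locations is not None:
            found &= counts <= self._max_locations
        return np.where(found, idx, -1)

    def hits_for_keys(self, keys: np.ndarray) -> np.ndarray:
        """All locations of the given bucket keys, merged and sorted."""
        if len(keys) == 0 or len(self._keys) == 0:
            return np.empty(0, dtype=_U64)
        idx = self._find(np.asarray(keys, dtype=_U64))
        parts = [
            self._flat[self._offsets[i] : self._offsets[i + 1]] for i in idx if i >= 0
        ]
        if not parts:
            return np.empty(0, dtype=_U64)
        return np.sort(np.concatenate(parts), kind="stable")

    def lookup_key(self, key: int) -> np.ndarray:
        i = int(self._find(np.array([key], dtype=_U64))[0])
        if i < 0:
            return np.empty(0, dtype=_U64)
        return self._flat[self._offsets[i] : self._offsets[i + 1]]

    def lookup(self, feature: int) -> list[Location]:
        key = int(_splitmix64(_U64(feature) ^ self._h2_seed))
        return [_unpack(p) for p in self.lookup_key(key)]

    def __len__(self) -> int:
        return len(self._keys)

    @property
    def _table(self) -> dict[int, np.ndarray]:
        """Dict view of the table (diagnostics and tests; not a hot path)."""
        return {
            int(k): self._flat[self._offsets[i] : self._offsets[i + 1]]
            for i, k in enumerate(self._keys)
        }

    # ---- (de)serialisation helpers -------------------------------------

    def _to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._keys, np.diff(self._offsets), self._flat

    @classmethod
    def _from_arrays(cls, h2_seed, max_locations, keys, counts, flat) -> "FeatureTable":
        t = cls(h2_seed, max_locations)
        t._keys = np.asarray(keys, dtype=_U64)
        t._offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        t._flat = np.asarray(flat, dtype=_U64)
        return t

    @classmethod
    def _from_flat(
        cls, h2_seed, max_locations, keys: np.ndarray, locs: np.ndarray
    ) -> "FeatureTable":
        """Bulk construction from parallel (bucket key, packed location) arrays."""
        t = cls(h2_seed, max_locations)
        if len(keys) == 0:
            return t
        order = np.lexsort((locs, keys))
        keys, locs = keys[order], locs[order]
        # drop duplicate (key, location) pairs
        keep = np.ones(len(keys), dtype=bool)
        keep[1:] = (keys[1:] != keys[:-1]) | (locs[1:] != locs[:-1])
        keys, locs = keys[keep], locs[keep]
        bounds = np.concatenate(
            [[0], np.flatnonzero(keys[1:] != keys[:-1]) + 1, [len(keys)]]
        ).astype(np.int64)
        t._keys = keys[bounds[:-1]]
        t._offsets = bounds
        t._flat = locs
        return t


@dataclass
class ReferenceIndex:
    """The full 3N reference index: both orientation tables plus metadata.

    ``forward_table`` indexes convert(ref); ``reverse_table`` indexes
    convert(reverse_complement(ref)).  Window IDs in the reverse table count
    from the 3′ end of the forward sequence.  The original (unconverted)
    reference sequences are retained for the alignment and MSA stages.
    """

    params: IndexParams
    scheme: ConversionScheme
    forward_table: FeatureTable
    reverse_table: FeatureTable
    target_names: list[str]
    target_seqs: list[str]

    @property
    def target_lengths(self) -> list[int]:
        return [len(s) for s in self.target_seqs]

    def n_windows(self, target_id: int) -> int:
        L = self.target_lengths[target_id]
        if L < self.params.k:
            return 0
        return (L - self.params.k) // self.params.stride + 1


def _bulk_window_keys(seq_3n: str, params: IndexParams) -> tuple[np.ndarray, np.ndarray]:
    """h2 bucket keys of every window's sketch, computed in bulk.

    Returns parallel arrays (window_id, key): one row per retained sketch
    feature.  Equivalent to sketching each window separately (distinct
    bottom-s of the h1 values, N k-mers skipped) but vectorised: windows
    are stacked into a matrix, row-sorted, de-duplicated by a second sort
    after masking repeats, and truncated to s columns.
    """
    codes = encode(seq_3n)
    H = kmer_hashes_positional(codes, params)
    n = len(H)
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=_U64)
    stride, npw = params.stride, params.w - params.k + 1
    n_win = (n - 1) // stride + 1
    idx = np.arange(n_win)[:, None] * stride + np.arange(npw)[None, :]
    M = np.full((n_win, npw), _SENTINEL, dtype=_U64)
    valid = idx < n
    M[valid] = H[idx[valid]]
    M.sort(axis=1)
    dup = np.zeros_like(M, dtype=bool)
    dup[:, 1:] = M[:, 1:] == M[:, :-1]
    M[dup] = _SENTINEL
    M.sort(axis=1)
    S = M[:, : params.s]
    wid, col = np.nonzero(S != _SENTINEL)
    keys = _splitmix64(S[wid, col] ^ params.h2_seed)
    return wid.astype(np.int64), keys


_SENTINEL = _U64(0xFFFFFFFFFFFFFFFF)


def kmer_hashes_positional(seq_codes: np.ndarray, params: IndexParams) -> np.ndarray:
    """Like :func:`kmer_hashes` but positional: invalid k-mers → sentinel."""
    k = params.k
    n = len(seq_codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64)
    valid = seq_codes != 4
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        ok &= valid[j : j + n]
    codes = np.where(valid, seq_codes, 0).astype(_U64)
    code = np.zeros(n, dtype=_U64)
    for j in range(k):
        code = (code << _U64(2)) | codes[j : j + n]
    out = _splitmix64(code ^ params.h1_seed)
    out[~ok] = _SENTINEL
    return out


def build_index(
    references: Sequence[tuple[str, str]],
    scheme: ConversionScheme,
    params: IndexParams | None = None,
) -> ReferenceIndex:
    """Build both orientation tables from (name, sequence) records.

    Each record is 3N-converted (forward, and separately its reverse
    complement), windowed, sketched, and its features inserted under their
    h2 bucket keys.  Records shorter than ``k`` are skipped.  Deterministic
    given (references, scheme, params).
    """
    if params is None:
        params = IndexParams()
    refs = [(n, s.upper()) for n, s in references]
    if not refs:
        raise ValueError("empty reference set")
    if all(len(s) < params.k for _, s in refs):
        raise ValueError(f"no reference record of length >= k={params.k}")
    flat: dict[str, list[list[np.ndarray]]] = {"fwd": [[], []], "rev": [[], []]}
    for tid, (_, seq) in enumerate(refs):
        if len(seq) < params.k:
            continue
        for which, seq_3n in (
            ("fwd", convert_3n(seq, scheme)),
            ("rev", convert_3n(reverse_complement(seq), scheme)),
        ):
            wids, keys = _bulk_window_keys(seq_3n, params)
            flat[which][0].append(keys)
            flat[which][1].append((np.int64(tid) << 32 | wids).astype(_U64))

    def _table(which: str) -> FeatureTable:
        keys = np.concatenate(flat[which][0]) if flat[which][0] else np.empty(0, _U64)
        locs = np.concatenate(flat[which][1]) if flat[which][1] else np.empty(0, _U64)
        return FeatureTable._from_flat(
            params.h2_seed, params.max_locations_per_feature, keys, locs
        )

    fwd, rev = _table("fwd"), _table("rev")
    return ReferenceIndex(
        params=params,
        scheme=scheme,
        forward_table=fwd,
        reverse_table=rev,
        target_names=[n for n, _ in refs],
        target_seqs=[s for _, s in refs],
    )


def lookup(table: FeatureTable, feature: int) -> list[Location]:
    """Locations stored for ``feature`` (empty when absent); never raises."""
    return table.lookup(feature)


# ---------------------------------------------------------------------------
# serialisation


def save_index(index: ReferenceIndex, path: str) -> None:
    """Write the index to a single .npz archive with a version header."""
    fk, fc, ff = index.forward_table._to_arrays()
    rk, rc, rf = index.reverse_table._to_arrays()
    meta = {
        "format_version": _INDEX_FORMAT_VERSION,
        "params": {
            "w": index.params.w,
            "k": index.params.k,
            "s": index.params.s,
            "hash_seed": index.params.hash_seed,
            "max_locations_per_feature": index.params.max_locations_per_feature,
        },
        "scheme": index.scheme.name,
        "target_names": index.target_names,
    }
    seq_blob = "".join(index.target_seqs).encode("ascii")
    seq_lens = np.array(index.target_lengths, dtype=np.int64)
    with open(path, "wb") as fh:
        np.savez(
            fh,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            seq_blob=np.frombuffer(seq_blob, dtype=np.uint8),
            seq_lens=seq_lens,
            fwd_keys=fk, fwd_counts=fc, fwd_flat=ff,
            rev_keys=rk, rev_counts=rc, rev_flat=rf,
        )


def load_index(path: str) -> ReferenceIndex:
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    meta = json.loads(bytes(data["meta"]).decode())
    if meta["format_version"] != _INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {meta['format_version']}")
    params = IndexParams(**meta["params"])
    scheme = ConversionScheme.from_name(meta["scheme"])
    blob = bytes(data["seq_blob"]).decode("ascii")
    seqs, pos = [], 0
    for L in data["seq_lens"]:
        seqs.append(blob[pos : pos + int(L)])
        pos += int(L)
    fwd = FeatureTable._from_arrays(
        params.h2_seed, params.max_locations_per_feature,
        data["fwd_keys"], data["fwd_counts"], data["fwd_flat"],
    )
    rev = FeatureTable._from_arrays(
        params.h2_seed, params.max_locations_per_feature,
        data["rev_keys"], data["rev_counts"], data["rev_flat"],
    )
    return ReferenceIndex(params, scheme, fwd, rev, meta["target_names"], seqs)
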