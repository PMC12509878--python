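import numpy as np
import pytest

from ncmap.index import (
    IndexParams,
    Location,
    build_index,
    kmer_hashes,
    load_index,
    lookup,
    save_index,
    sketch,
    windows,
)
from ncmap.seqcore import ConversionScheme, encode

from conftest import random_seq


def all_kmers(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


class TestWindows:
    def test_single_window_exact_length(self):
        p = IndexParams(w=64, k=16)
        seq = "A" * 64
        out = list(windows(seq, p))
        assert out == [(0, 0, seq)]

    def test_len100_two_windows(self):
        p = IndexParams(w=64, k=16)
        seq = random_seq(np.random.default_rng(0), 100)
        out = list(windows(seq, p))
        assert [(w, o, len(s)) for w, o, s in out] == [(0, 0, 64), (1, 49, 51)]

    def test_too_short_yields_nothing(self):
        assert list(windows("A" * 15, IndexParams(k=16))) == []

    @pytest.mark.parametrize("n", [16, 64, 65, 100, 333, 1000])
    def test_kmer_tiling_exactly_once(self, rng, n):
        """Each k-mer of the sequence lies in exactly one window."""
        p = IndexParams(w=64, k=16)
        seq = random_seq(rng, n)
        tiled = []
        for _, off, wseq in windows(seq, p):
            tiled.extend(all_kmers(wseq, p.k))
        assert tiled == all_kmers(seq, p.k)


class TestSketch:
    def test_few_distinct_hashes_all_returned(self):
        p = IndexParams(w=64, k=16, s=16)
        # single distinct k-mer
        sk = sketch("C" * 64, p)
        assert len(sk) == 1

    def test_deterministic(self, rng):
        p = IndexParams()
        w = random_seq(rng, 64)
        assert sketch(w, p) == sketch(w, p)

    def test_matches_bruteforce_bottom_s(self, rng):
        """Sketch equals: hash all k-mers with h1, dedupe, sort, take s."""
        p = IndexParams(w=64, k=16, s=16)
        for _ in range(20):
            w = random_seq(rng, 64)
            h = [int(kmer_hashes(encode(km), p)[0]) for km in all_kmers(w, p.k)]
            expected = sorted(set(h))[: p.s]
            assert sketch(w, p) == expected

    def test_n_kmers_skipped(self, rng):
        p = IndexParams(w=64, k=16)
        assert sketch("N" * 64, p) == []
        # an N in the middle removes exactly the k-mers overlapping it
        clean = random_seq(rng, 64)
        dirty = clean[:32] + "N" + clean[33:]
        valid = [km for km in all_kmers(dirty, p.k) if "N" not in km]
        h = sorted({int(kmer_hashes(encode(km), p)[0]) for km in valid})[: p.s]
        assert sketch(dirty, p) == h

    def test_sketch_is_ascending_and_bounded(self, rng):
        p = IndexParams(s=5)
        for _ in range(10):
            sk = sketch(random_seq(rng, 64), p)
            assert sk == sorted(sk) and len(sk) <= 5


class TestBuildIndex:
    def test_c_free_record_forward_locations(self, ct_scheme, rng):
        seq = "".join(rng.choice(list("AGT"), size=64))
        idx = build_index([("r", seq)], ct_scheme, IndexParams())
        assert 1 <= len(idx.forward_table) <= 16
        locs = {tuple(l) for f in sketch(seq, idx.params) for l in lookup(idx.forward_table, f)}
        assert locs == {(0, 0)}

    def test_two_identical_records_symmetric_locations(self, ct_scheme, rng):
        seq = random_seq(rng, 150)
        idx = build_index([("a", seq), ("b", seq)], ct_scheme, IndexParams())
        from ncmap.seqcore import convert_3n

        for wid, _, wseq in windows(convert_3n(seq, ct_scheme), idx.params):
            for f in sketch(wseq, idx.params):
                locs = lookup(idx.forward_table, f)
                mine = [l for l in locs if l.window_id == wid]
                assert Location(0, wid) in locs and Location(1, wid) in locs

    def test_all_cytosine_collapses_to_one_feature(self, ct_scheme):
        idx = build_index([("c", "C" * 64)], ct_scheme, IndexParams())
        assert len(idx.forward_table) == 1

    def test_empty_and_invalid_references(self, ct_scheme):
        with pytest.raises(ValueError):
            build_index([], ct_scheme, IndexParams())
        with pytest.raises(ValueError):
            build_index([("x", "ACGTR" * 20)], ct_scheme, IndexParams())

    def test_deterministic_rebuild(self, ct_scheme, rng):
        refs = [("r", random_seq(rng, 500))]
        a = build_index(refs, ct_scheme, IndexParams())
        b = build_index(refs, ct_scheme, IndexParams())
        da, db = a.forward_table._table, b.forward_table._table
        assert sorted(da) == sorted(db)
        for k in da:
            assert np.array_equal(da[k], db[k])


class TestLookup:
    def test_absent_feature_empty(self, ct_scheme):
        idx = build_index([("r", "ACGT" * 32)], ct_scheme, IndexParams())
        stored = set(idx.forward_table._table)
        probe = 999_983  # arbitrary feature value
        while int(idx.forward_table.h2(np.array([probe], dtype=np.uint64))[0]) in stored:
            probe += 1
        assert lookup(idx.forward_table, probe) == []

    def test_lookup_matches_rebuilt_sketches(self, ct_scheme, rng):
        """For every stored feature, lookup equals the windows containing it."""
        from ncmap.seqcore import convert_3n

        refs = [("a", random_seq(rng, 400)), ("b", random_seq(rng, 300))]
        params = IndexParams(max_locations_per_feature=None)
        idx = build_index(refs, ct_scheme, params)
        expected: dict[int, set] = {}
        for tid, (_, seq) in enumerate(refs):
            for wid, _, wseq in windows(convert_3n(seq, ct_scheme), params):
                for f in sketch(wseq, params):
                    expected.setdefault(f, set()).add((tid, wid))
        for f, locs in expected.items():
            got = {tuple(l) for l in lookup(idx.forward_table, f)}
            assert got == locs
        # and location lists are sorted ascending
        for f in expected:
            got = lookup(idx.forward_table, f)
            assert got == sorted(got)


def test_serialization_roundtrip(tmp_path, small_index):
    path = str(tmp_path / "idx.npz")
    save_index(small_index, path)
    loaded = load_index(path)
    assert loaded.params == small_index.params
    assert loaded.scheme == small_index.scheme
    assert loaded.target_names == small_index.target_names
    assert loaded.target_seqs == small_index.target_seqs
    da, db = small_index.forward_table._table, loaded.forward_table._table
    assert sorted(da) == sorted(db)
    for k in da:
        assert np.array_equal(da[k], db[k])


def test_sketch_overlap_tracks_jaccard(rng):
    """Sketch intersection grows (on average) with true k-mer Jaccard."""
    p = IndexParams(w=64, k=16, s=16)
    by_overlap = {}
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        sims = []
        for _ in range(40):
            a = random_seq(rng, 64)
            cut = int(64 * frac)
            b = a[:cut] + random_seq(rng, 64 - cut)
            sa, sb = set(sketch(a, p)), set(sketch(b, p))
            sims.append(len(sa & sb))
        by_overlap[frac] = np.mean(sims)
    vals = [by_overlap[f] for f in sorted(by_overlap)]
    assert all(x <= y + 1e-9 for x, y in zip(vals, vals[1:]))
    assert by_overlap[1.0] > by_overlap[0.0]
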