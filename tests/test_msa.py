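import pickle

import numpy as np
import pytest

from ncmap.msa import (
    AlignedRead,
    ForestModel,
    FEATURE_NAMES,
    build_msa,
    column_stats,
    count_conversions,
    conversion_positions,
    feature_vector,
    filter_region,
    global_stats,
    read_stats,
    rf_classify,
    rf_train,
)
from ncmap.seqcore import ConversionScheme

CT = ConversionScheme("C", "T")


def mk(read_id, seq, gstart, cigar, strand="+", score=1.0, conv_strand="+", mate=0):
    gend = gstart + sum(
        int(n) for n, op in __import__("re").findall(r"(\d+)([=XIDM])", cigar) if op in "=XMD"
    )
    return AlignedRead(
        read_id=read_id, mate=mate, seq=seq, strand=strand, target_id=0,
        gstart=gstart, gend=gend, cigar=cigar, score=score,
        edit_distance=0, conv_strand=conv_strand,
    )


class TestBuildMSA:
    def test_single_exact_read_padded(self):
        msa = build_msa("AAACGTAAA", 0, [mk("r1", "CGT", 3, "3=")])
        assert msa.region_row == "AAACGTAAA"
        assert msa.rows == ["   CGT   "]

    def test_more_than_16_reads_truncated_by_score(self):
        reads = [mk(f"r{i:02d}", "CGT", 3, "3=", score=1.0 - i * 0.01) for i in range(20)]
        msa = build_msa("AAACGTAAA", 0, reads)
        assert msa.n_reads == 16
        assert {m.read_id for m in msa.reads} == {f"r{i:02d}" for i in range(16)}

    def test_insertion_adds_one_reference_gap_column(self):
        msa = build_msa("ACGT", 0, [mk("r1", "ACXGT".replace("X", "A"), 0, "2=1I2=")])
        assert msa.region_row == "AC-GT"
        assert msa.rows == ["ACAGT"]
        assert list(msa.ref_positions) == [0, 1, -1, 2, 3]

    def test_deletion_shown_as_gap(self):
        msa = build_msa("ACGTA", 0, [mk("r1", "ACTA", 0, "2=1D2=")])
        assert msa.rows == ["AC-TA"]

    def test_minus_strand_row_is_revcomp(self):
        msa = build_msa("ACGT", 0, [mk("r1", "ACGT", 0, "4=", strand="-")])
        assert msa.rows == ["ACGT"]
        assert msa.reads[0].seq == "ACGT"
        msa2 = build_msa("AAAA", 0, [mk("r2", "TTTT", 0, "4=", strand="-")])
        assert msa2.rows == ["AAAA"]

    def test_inconsistent_cigar_rejected(self):
        with pytest.raises(ValueError):
            build_msa("ACGT", 0, [mk("r1", "ACGTA", 0, "4=")])

    def test_shared_insertion_block(self):
        reads = [
            mk("r1", "ACAAGT", 0, "2=2I2=", score=0.9),
            mk("r2", "ACGT", 0, "4="),
        ]
        msa = build_msa("ACGT", 0, reads)
        assert msa.region_row == "AC--GT"
        byid = dict(zip([m.read_id for m in msa.reads], msa.rows))
        assert byid["r1"] == "ACAAGT"
        assert byid["r2"] == "AC--GT"


class TestColumnStats:
    def msa4(self):
        return build_msa(
            "C", 0, [mk(f"r{i}", b, 0, "1=") for i, b in enumerate("CCCC")]
        )

    def test_unanimous_column(self):
        cs = column_stats(self.msa4(), 0, consensus_threshold=0.8)
        assert (cs.coverage, cs.frac_c, cs.most_common) == (4, 100.0, "C")
        assert cs.m_agrees_ref and cs.consensus == "C"

    def test_majority_below_threshold_no_consensus(self):
        msa = build_msa("C", 0, [mk(f"r{i}", b, 0, "1=") for i, b in enumerate("TTC")])
        cs = column_stats(msa, 0, consensus_threshold=0.8)
        assert cs.most_common == "T"
        assert not cs.m_agrees_ref
        assert cs.consensus is None
        assert abs(cs.frac_t - 200 / 3) < 1e-9

    def test_empty_column_all_gaps(self):
        msa = build_msa("AAACGT", 0, [mk("r1", "CGT", 3, "3=")])
        cs = column_stats(msa, 0)
        assert (cs.coverage, cs.most_common, cs.consensus) == (0, None, None)

    def test_tie_goes_to_reference_base(self):
        msa = build_msa("C", 0, [mk("r0", "C", 0, "1="), mk("r1", "T", 0, "1=")])
        cs = column_stats(msa, 0)
        assert cs.most_common == "C" and cs.m_agrees_ref


class TestReadStats:
    def test_conversion_not_a_deviation(self):
        msa = build_msa("ACGT", 0, [mk("r1", "ATGT", 0, "1=1X2=")])
        rs = read_stats(msa, 0, CT)
        assert rs.pct_dev_ref == 0.0

    def test_real_mismatch_counts(self):
        msa = build_msa("ACGT", 0, [mk("r1", "AGGT", 0, "1=1X2=")])
        rs = read_stats(msa, 0, CT)
        assert rs.pct_dev_ref == 25.0

    def test_identical_read_zero_deviation(self):
        msa = build_msa("ACGT", 0, [mk("r1", "ACGT", 0, "4=")])
        rs = read_stats(msa, 0, CT)
        assert (rs.pct_dev_ref, rs.pct_dev_consensus) == (0.0, 0.0)

    def test_conversion_counts_as_deviation_when_flagged(self):
        msa = build_msa("ACGT", 0, [mk("r1", "ATGT", 0, "1=1X2=")])
        rs = read_stats(msa, 0, CT, conversions_are_deviations=True)
        assert rs.pct_dev_ref == 25.0

    def test_minus_conversion_strand_uses_complement_pair(self):
        # chemistry acted on the opposite strand: expected pattern is G->A
        msa = build_msa("ACGA", 0, [mk("r1", "ACAA", 0, "2=1X1=", conv_strand="-")])
        assert read_stats(msa, 0, CT).pct_dev_ref == 0.0
        # same alignment interpreted as forward-chemistry: a real mismatch
        msa2 = build_msa("ACGA", 0, [mk("r1", "ACAA", 0, "2=1X1=", conv_strand="+")])
        assert read_stats(msa2, 0, CT).pct_dev_ref == 25.0


class TestGlobalStats:
    def test_single_perfect_read(self):
        msa = build_msa("ACGT", 0, [mk("r1", "ACGT", 0, "4=")])
        assert global_stats(msa) == __import__("ncmap.msa", fromlist=["MSAGlobalStats"]).MSAGlobalStats(1, 1.0, 1.0, 1.0)

    def test_mean_of_two(self):
        msa = build_msa(
            "ACGT", 0,
            [mk("r1", "ACGT", 0, "4=", score=0.8), mk("r2", "ACGT", 0, "4=", score=1.0)],
        )
        g = global_stats(msa)
        assert (g.n_reads, g.min_score, g.avg_score, g.max_score) == (2, 0.8, 0.9, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_stats(build_msa("ACGT", 0, []))


class TestConversionCounting:
    def test_two_conversions(self):
        msa = build_msa("CCGG", 0, [mk("r1", "TTGG", 0, "2X2=")])
        assert count_conversions(msa, 0, CT) == 2
        assert conversion_positions(msa, 0, CT) == [0, 1]

    def test_no_conversion(self):
        msa = build_msa("CCGG", 0, [mk("r1", "CCGG", 0, "4=")])
        assert count_conversions(msa, 0, CT) == 0

    def test_minus_chemistry_complement_pair(self):
        msa = build_msa("CCGG", 0, [mk("r1", "CCAA", 0, "2=2X", conv_strand="-")])
        assert count_conversions(msa, 0, CT) == 2
        assert conversion_positions(msa, 0, CT) == [2, 3]


class TestForest:
    def sep_data(self, rng, n=200):
        X = rng.normal(size=(n, len(FEATURE_NAMES)))
        y = (X[:, 0] >= 0).astype(int)
        return X, y

    def test_separable_data_perfect_training_accuracy(self, rng):
        X, y = self.sep_data(rng)
        model = rf_train(X, y, n_trees=25, seed=0)
        preds = [rf_classify(model, x)[1] for x in X]
        assert np.mean(np.array(preds) == y.astype(bool)) == 1.0

    def test_identical_instances_predict_prior(self, rng):
        X = np.zeros((10, len(FEATURE_NAMES)))
        y = np.array([1, 1, 1, 0, 0, 0, 1, 1, 0, 1])
        model = rf_train(X, y, n_trees=400, seed=1)
        p, _ = rf_classify(model, X[0])
        assert abs(p - y.mean()) < 0.08  # bootstrap noise around the prior

    def test_same_seed_identical_model_bytes(self, rng):
        X, y = self.sep_data(rng)
        m1 = rf_train(X, y, n_trees=10, seed=7)
        m2 = rf_train(X, y, n_trees=10, seed=7)
        assert pickle.dumps(m1) == pickle.dumps(m2)

    def test_probability_is_mean_over_trees(self, rng):
        X, y = self.sep_data(rng)
        model = rf_train(X, y, n_trees=15, seed=3)
        x = rng.normal(size=len(FEATURE_NAMES))
        p, _ = rf_classify(model, x)
        pos = int(np.flatnonzero(model.forest.classes_ == 1)[0])
        per_tree = [t.predict_proba(x.reshape(1, -1))[0, pos] for t in model.forest.estimators_]
        assert abs(p - np.mean(per_tree)) < 1e-12

    def test_boundary_probability_keeps(self, rng):
        X, y = self.sep_data(rng)
        model = rf_train(X, y, n_trees=5, seed=0)
        from dataclasses import replace

        x = X[0]
        p, _ = rf_classify(model, x)
        at_threshold = replace(model, decision_threshold=p)
        assert rf_classify(at_threshold, x)[1] is True

    def test_dimension_mismatch_rejected(self, rng):
        X, y = self.sep_data(rng)
        model = rf_train(X, y, n_trees=5, seed=0)
        with pytest.raises(ValueError):
            rf_classify(model, np.zeros(3))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, len(FEATURE_NAMES)))
        with pytest.raises(ValueError):
            rf_train(X, np.ones(20))


class TestFilterRegion:
    def test_singleton_score_rule(self):
        good = build_msa("ACGT", 0, [mk("r1", "ACGT", 0, "4=", score=0.95)])
        bad = build_msa("ACGT", 0, [mk("r1", "ACGT", 0, "4=", score=0.5)])
        assert filter_region(good, None, min_score=0.8) == [(True, None)]
        assert filter_region(bad, None, min_score=0.8) == [(False, None)]

    def test_multi_read_decisions_match_rf_classify(self, rng):
        X = rng.normal(size=(100, len(FEATURE_NAMES)))
        y = (X[:, 1] > 0).astype(int)
        model = rf_train(X, y, n_trees=10, seed=0)
        reads = [mk(f"r{i}", "ACGT", 0, "4=", score=0.9 + 0.01 * i) for i in range(3)]
        msa = build_msa("ACGT", 0, reads)
        decisions = filter_region(msa, model, min_score=0.8, scheme=CT)
        for i, (keep, p) in enumerate(decisions):
            vec = feature_vector(msa, i, CT)
            p2, keep2 = rf_classify(model, vec)
            assert abs(p - p2) < 1e-12 and keep == keep2

    def test_context_dependence_can_flip_decision(self, rng):
        """A mapping's fate in a multi-read region depends on its co-mapped
        reads: changing them changes the feature vector and, for a
        borderline probability, the keep decision."""
        from dataclasses import replace

        X = rng.normal(size=(300, len(FEATURE_NAMES)))
        # decision driven by deviation-from-consensus and region size
        y = ((X[:, 2] < 0) & (X[:, 3] > 0)).astype(int)
        model = rf_train(X, y, n_trees=30, seed=2)
        ref = "ACGTACGTAC"
        focal = mk("r0", "AGGTACGTAC", 0, "1=1X8=", score=0.9)
        agree = [mk(f"a{i}", "AGGTACGTAC", 0, "1=1X8=") for i in range(4)]
        oppose = [mk(f"b{i}", "ACGTACGTAC", 0, "10=") for i in range(4)]
        msa_a = build_msa(ref, 0, [focal] + agree)
        msa_b = build_msa(ref, 0, [focal] + oppose)
        ia = [m.read_id for m in msa_a.reads].index("r0")
        ib = [m.read_id for m in msa_b.reads].index("r0")
        pa = filter_region(msa_a, model, scheme=CT)[ia][1]
        pb = filter_region(msa_b, model, scheme=CT)[ib][1]
        assert pa != pb
        mid = (pa + pb) / 2
        flipping = replace(model, decision_threshold=mid)
        ka = filter_region(msa_a, flipping, scheme=CT)[ia][0]
        kb = filter_region(msa_b, flipping, scheme=CT)[ib][0]
        assert ka != kb

    def test_model_none_multiread_uses_score_rule(self):
        reads = [
            mk("r1", "ACGT", 0, "4=", score=0.95),
            mk("r2", "ACGT", 0, "4=", score=0.5),
        ]
        msa = build_msa("ACGT", 0, reads)
        assert filter_region(msa, None, min_score=0.8) == [(True, None), (False, None)]


def test_feature_vector_shape_and_finiteness(rng):
    reads = [mk(f"r{i}", "ACGT", 0, "4=") for i in range(3)]
    msa = build_msa("ACGT", 0, reads)
    for i in range(3):
        v = feature_vector(msa, i, CT)
        assert v.shape == (len(FEATURE_NAMES),)
        assert np.all(np.isfinite(v))
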