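import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfusion.data_model import SplitSpec
from emgfusion.fusion_eval import (
    AccuracyTable,
    build_verification_task,
    fuse_score_matrix,
    fuse_scores,
    identification_accuracy,
    improvement_report,
    paired_t_test,
    summary_stats,
)
from emgfusion.published import (
    ENSEMBLES,
    STREAMS,
    published_accuracy_table,
    single_proposed_pairs,
)

from conftest import label_manifest


class TestFuseScores:
    def test_sum_and_product_arithmetic(self):
        a, b = [0.6, 0.4], [0.2, 0.8]
        s = fuse_scores(a, b, "sum")
        np.testing.assert_allclose(s.fused_scores, [0.8, 1.2])
        assert s.predicted_class == 1
        p = fuse_scores(a, b, "product")
        np.testing.assert_allclose(p.fused_scores, [0.12, 0.32])
        assert p.predicted_class == 1

    def test_uniform_partner_preserves_ranking(self, rng):
        for _ in range(50):
            a = rng.dirichlet(np.ones(7))
            u = np.full(7, 1 / 7)
            for mode in ("sum", "product"):
                fused = fuse_scores(a, u, mode).fused_scores
                np.testing.assert_array_equal(np.argsort(fused), np.argsort(a))

    def test_length_mismatch_and_mode_errors(self):
        with pytest.raises(ValueError):
            fuse_scores([0.5, 0.5], [1.0], "sum")
        with pytest.raises(ValueError):
            fuse_scores([0.5, 0.5], [0.5, 0.5], "mean")

    def test_tie_breaks_to_lowest_index(self):
        assert fuse_scores([0.5, 0.5], [0.5, 0.5], "sum").predicted_class == 0

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(0, 10_000))
    def test_argmax_agreement_preserved(self, seed):
        r = np.random.default_rng(seed)
        c = int(r.integers(2, 12))
        a, b = r.dirichlet(np.ones(c)), r.dirichlet(np.ones(c))
        if np.argmax(a) == np.argmax(b):
            k = int(np.argmax(a))
            assert fuse_scores(a, b, "sum").predicted_class == k
            assert fuse_scores(a, b, "product").predicted_class == k

    def test_product_never_selects_zeroed_class(self, rng):
        for _ in range(100):
            a = rng.dirichlet(np.ones(5))
            b = rng.dirichlet(np.ones(5))
            z = int(rng.integers(5))
            b[z] = 0.0
            if np.any(a * b > 0):
                assert fuse_scores(a, b, "product").predicted_class != z

    def test_matrix_fusion_matches_vector_fusion(self, rng):
        a = rng.dirichlet(np.ones(4), size=10)
        b = rng.dirichlet(np.ones(4), size=10)
        for mode in ("sum", "product"):
            m = fuse_score_matrix(a, b, mode)
            for i in range(10):
                np.testing.assert_allclose(m[i], fuse_scores(a[i], b[i], mode).fused_scores)


class TestAccuracy:
    def test_examples(self):
        assert identification_accuracy([1, 2, 3], [1, 2, 3]) == 100.0
        assert identification_accuracy([1, 1], [2, 3]) == 0.0
        assert identification_accuracy([1, 2, 3, 4], [1, 2, 3, 0]) == 75.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identification_accuracy([], [])


class TestVerification:
    @pytest.mark.parametrize("n_subjects,expected_neg", [(100, 99), (2, 1)])
    def test_one_sample_per_other_subject(self, n_subjects, expected_neg):
        manifest = label_manifest(n_subjects, 2, 1, 5)
        split = SplitSpec([1, 2, 3], [4, 5])
        tr, ytr, te, yte = build_verification_task(manifest, "s000", split)
        assert sum(1 for y in ytr if y == 0) == expected_neg
        assert sum(1 for y in yte if y == 0) == expected_neg
        # positives: all target records on each side of the split
        assert sum(ytr) == 2 * 3 and sum(yte) == 2 * 2
        assert all(e.subject_id != "s000" for e, y in zip(te, yte) if y == 0)

    def test_unknown_subject_rejected(self):
        manifest = label_manifest(3, 1, 1, 4)
        with pytest.raises(ValueError):
            build_verification_task(manifest, "nope", SplitSpec([1, 2], [3, 4]))


class TestSummaryStats:
    def test_published_single_stream_statistics(self):
        table = published_accuracy_table()
        mean, sd, var = summary_stats(table, STREAMS)
        assert mean == pytest.approx(72.73, abs=0.005)
        assert sd == pytest.approx(14.53, abs=0.005)
        assert var == pytest.approx(211.01, abs=0.005)

    def test_identical_entries_zero_sd(self):
        t = AccuracyTable([("d", "a", 50.0), ("d", "b", 50.0)])
        _, sd, var = summary_stats(t)
        assert sd == 0.0 and var == 0.0

    def test_single_entry_rejected(self):
        with pytest.raises(ValueError):
            summary_stats(AccuracyTable([("d", "a", 50.0)]))

    def test_accuracy_bounds_enforced(self):
        with pytest.raises(ValueError):
            AccuracyTable([("d", "a", 101.0)])


class TestPairedTTest:
    def test_published_pairs_reproduce_printed_statistics(self):
        res = paired_t_test(single_proposed_pairs())
        assert res.mean_diff == pytest.approx(10.76, abs=0.005)
        assert res.p_value == pytest.approx(0.0217, abs=0.0001)
        assert res.h == 1 and res.df == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([(50.0, 55.0), (60.0, 65.0)])

    def test_h_zero_when_not_significant(self):
        res = paired_t_test([(50.0, 51.0), (60.0, 58.0), (70.0, 71.5)])
        assert res.h == 0 and res.p_value > 0.05


class TestImprovementReport:
    def test_published_gaps(self):
        rep = improvement_report(
            published_accuracy_table(),
            ensemble_methods=list(ENSEMBLES),
            stream_methods=list(STREAMS),
            baseline_methods=["EmgPCA-L2"],
        )
        by = {(r.dataset, r.comparison): r.gap for r in rep.itertuples(index=False)}
        assert by[("angeles", "max_ensemble_vs_stream")] == pytest.approx(10.90, abs=0.005)
        assert by[("angeles", "best_ensemble_vs_baseline")] == pytest.approx(28.35, abs=0.005)
        assert by[("cu", "best_ensemble_vs_baseline")] == pytest.approx(33.17, abs=0.005)

    def test_missing_method_rejected(self):
        t = AccuracyTable([("d", "EmgCNN", 80.0)])
        with pytest.raises(ValueError, match="missing"):
            improvement_report(t)

    def test_single_method_table_gives_empty_report(self):
        t = AccuracyTable([("d", "only", 80.0)])
        rep = improvement_report(t, ensemble_methods=[], stream_methods=[], baseline_methods=[])
        assert rep.empty
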