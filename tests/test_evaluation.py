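"""Participant-level splitting, metrics, and the statistical toolkit."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import eeggcn as e
from eeggcn.evaluation import (
    SplitPlan,
    auc_score,
    bh_adjust,
    cohens_d,
    compute_metrics,
    delong_test,
    kfold_cv,
    stats_suite,
    subject_split,
)


class TestSubjectSplit:
    def test_default_cohort_gives_520_train_130_test_segments(self, default_ds):
        plan = subject_split(default_ds, 0.2, seed=0)
        tr, te = plan.apply(default_ds)
        assert default_ds.n_segments == 650
        assert tr.n_segments == 520 and te.n_segments == 130

    def test_windows_inherit_their_subjects_assignment(self, default_ds):
        plan = subject_split(default_ds, 0.2, seed=3)
        tr, te = plan.apply(default_ds)
        assert set(tr.subject_ids) == set(plan.train_subjects)
        assert set(te.subject_ids) == set(plan.test_subjects)
        assert not set(tr.subject_ids) & set(te.subject_ids)

    def test_stratification_keeps_both_classes_in_test(self, default_ds):
        for seed in range(5):
            _, te = subject_split(default_ds, 0.2, seed=seed).apply(default_ds)
            assert len(np.unique(te.y)) == 2

    def test_plan_with_overlap_is_rejected(self):
        with pytest.raises(ValueError, match="both sides"):
            SplitPlan(("a",), (), 0.2, 0)
        with pytest.raises(ValueError, match="overlap|sides"):
            SplitPlan(("a", "b"), ("b",), 0.2, 0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_fraction_outside_unit_interval_errors(self, default_ds, frac):
        with pytest.raises(ValueError, match="test_fraction"):
            subject_split(default_ds, frac, seed=0)

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            subject_split({"s1": "AD", "s2": "HC"}, 0.5, seed=0)


class TestKFold:
    def test_52_subjects_give_fold_sizes_ten_and_eleven(self):
        subjects = [f"s{i}" for i in range(52)]
        folds = kfold_cv(subjects, k=5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [10, 10, 10, 11, 11]
        seen = [s for f in folds for s in f]
        assert sorted(seen) == sorted(subjects)

    def test_k_equal_to_subject_count_is_leave_one_out(self):
        folds = kfold_cv([f"s{i}" for i in range(6)], k=6, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_k_above_subject_count_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(["a", "b"], k=3)

    def test_cross_validate_returns_one_row_per_fold(self, tiny_ds):
        df = e.cross_validate(tiny_ds, k=3, seed=0,
                              train_config=e.TrainConfig(epochs=2, seed=0))
        assert list(df.index[:-2]) == [0, 1, 2]
        assert {"accuracy", "auc", "f1"} <= set(df.columns)
        assert "mean" in df.index and "sd" in df.index


class TestMetrics:
    def test_hand_computed_confusion_example(self):
        """TP=3, FP=1, FN=1, TN=5 -> Acc 80%, Pre 75%, Rec 75%, F1 75%."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4])
        rep = compute_metrics(y, p)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 5)
        assert rep.accuracy == pytest.approx(80.0)
        assert rep.precision == pytest.approx(75.0)
        assert rep.recall == pytest.approx(75.0)
        assert rep.f1 == pytest.approx(75.0)

    def test_perfect_separation_scores_100_everywhere(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        rep = compute_metrics(y, p)
        for v in (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.auc):
            assert v == pytest.approx(100.0)

    def test_random_scores_give_chance_auc(self, rng):
        y = (rng.random(4000) < 0.5).astype(int)
        p = rng.random(4000)
        assert abs(compute_metrics(y, p).auc - 50.0) < 5.0

    def test_midrank_auc_agrees_with_sklearn_under_ties(self, rng):
        y = (rng.random(300) < 0.4).astype(int)
        p = np.round(rng.random(300), 1)  # force ties
        assert auc_score(y, p) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_single_class_truth_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics(np.ones(4, dtype=int), np.full(4, 0.5))

    def test_f1_is_harmonic_mean_identity(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        p = rng.random(200)
        rep = compute_metrics(y, p)
        if rep.precision + rep.recall > 0:
            expected = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(expected)


class TestStatsToolkit:
    def test_cohens_d_of_identical_vectors_is_zero(self):
        a = np.array([0.8, 0.9, 0.85, 0.95])
        assert cohens_d(a, a.copy()) == 0.0

    def test_cohens_d_sign_follows_the_better_model(self, rng):
        a = rng.normal(0.9, 0.02, 50)
        b = rng.normal(0.7, 0.02, 50)
        assert cohens_d(a, b) > 0 > cohens_d(b, a)

    def test_bh_step_up_on_the_textbook_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, 0.04)

    def test_bh_is_monotone_in_raw_order(self, rng):
        p = rng.random(12)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_delong_identical_scores_give_p_one(self, rng):
        y = np.array([0, 1] * 20)
        p = rng.random(40)
        out = delong_test(y, p, p)
        assert out["p_value"] == 1.0 and out["auc_difference"] == 0.0

    def test_delong_detects_a_clearly_better_model(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        good = 0.8 * y + 0.2 * rng.random(200)
        bad = rng.random(200)
        out = delong_test(y, good, bad)
        assert out["auc_a"] > 0.9 and out["p_value"] < 1e-6

    def test_all_tied_fold_scores_are_rejected(self, rng):
        y = np.array([0, 1] * 10)
        p = rng.random(20)
        with pytest.raises(ValueError, match="tied"):
            stats_suite([0.8, 0.8], [0.8, 0.8], y, p, p)

    def test_stats_suite_reports_the_full_comparison(self, rng):
        y = (rng.random(120) < 0.5).astype(int)
        pa = 0.6 * y + 0.4 * rng.random(120)
        pb = 0.3 * y + 0.7 * rng.random(120)
        fa = rng.normal(0.9, 0.03, 5)
        fb = rng.normal(0.75, 0.03, 5)
        out = stats_suite(fa, fb, y, pa, pb)
        assert 0 <= out["wilcoxon_p"] <= 1
        assert out["cohens_d"] > 1.0
        assert out["auc_difference_pct"] > 0
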