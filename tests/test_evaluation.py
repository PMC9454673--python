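import numpy as np
import pytest

from sumosite import (
    ConfusionCounts,
    ModelConfig,
    MotifModel,
    SyntheticDatasetSpec,
    compute_metrics,
    confusion_at_threshold,
    cross_validate,
    evaluate_fixed_sp,
    generate_peptides,
    paired_t_test,
    roc_auc,
    run_sweep,
    threshold_for_specificity,
)


def brute_force_auc(scores, labels):
    """Independent oracle: direct pair counting over all (pos, neg) pairs."""
    s = np.asarray(scores, dtype=np.float64)
    l = np.asarray(labels)
    pos, neg = s[l == 1], s[l == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


class TestConfusionMetrics:
    def test_high_sensitivity_operating_point(self):
        # balanced confusion at Sn 0.802 / Sp 0.650
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(802, 650, 350, 198))
        assert (sn, sp) == (0.802, 0.650)
        assert acc == pytest.approx(0.726)
        assert mcc == pytest.approx(0.457, abs=5e-4)

    def test_no_association_gives_zero_mcc(self):
        _, _, acc, mcc = compute_metrics(ConfusionCounts(25, 25, 25, 25))
        assert mcc == 0.0 and acc == 0.5

    def test_perfect_prediction(self):
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(10, 10, 0, 0))
        assert (sn, sp, acc, mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_is_flagged_not_silent(self):
        with pytest.warns(RuntimeWarning, match="Sn undefined"):
            sn, *_ = compute_metrics(ConfusionCounts(0, 5, 5, 0))
        assert np.isnan(sn)

    def test_mcc_sign_follows_diagonal_product(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, 4)
            *_, mcc = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert (mcc > 0) == (tp * tn > fp * fn) or mcc == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 1, 1, 1)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_perfectly_wrong(self):
        assert roc_auc([0.4, 0.6], [1, 0]) == 0.0

    def test_ties_count_half(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_brute_force_oracle(self):
        for i in range(50):
            r = np.random.default_rng(i)
            n = int(r.integers(10, 201))
            labels = r.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(r.random(n), 2)  # rounding forces ties
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        from sklearn.metrics import roc_auc_score

        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestFixedSpecificity:
    def test_exact_quantile_on_grid(self):
        neg = np.arange(1, 101) / 100.0
        thr = threshold_for_specificity(neg, 0.65)
        assert np.sum(neg <= thr) == 65

    def test_median_at_half(self, rng):
        neg = rng.normal(size=1001)
        thr = threshold_for_specificity(neg, 0.5)
        assert thr == pytest.approx(np.median(neg))

    def test_degenerate_ties_flagged(self):
        with pytest.warns(RuntimeWarning, match="tied scores"):
            threshold_for_specificity(np.ones(50), 0.65)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            threshold_for_specificity([0.5], 1.2)

    def test_random_scores_give_sn_complement_of_sp(self, rng):
        n = 20000
        scores = rng.random(2 * n)
        labels = np.array([1] * n + [0] * n)
        m = evaluate_fixed_sp(scores, labels, 0.650)
        # under the null Sn ~ Binomial(n, 0.35)/n; allow 3 sd
        sd3 = 3 * np.sqrt(0.35 * 0.65 / n)
        assert m.sn == pytest.approx(0.35, abs=sd3)
        assert abs(m.mcc) < 0.03
        assert m.sp == pytest.approx(0.650, abs=1.0 / n)

    def test_perfect_scores(self):
        labels = np.array([1] * 50 + [0] * 50)
        scores = labels + np.linspace(0, 0.4, 100)
        m = evaluate_fixed_sp(scores, labels)
        assert m.sn == 1.0 and m.auc == 1.0

    def test_balanced_acc_is_mean_of_sn_sp(self, rng):
        scores = rng.random(400)
        labels = np.array([1, 0] * 200)
        m = evaluate_fixed_sp(scores, labels)
        assert m.acc == pytest.approx((m.sn + m.sp) / 2, abs=1e-12)

    def test_threshold_monotonicity(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        prev_sn, prev_sp = 1.0, 0.0
        for thr in np.linspace(0, 1, 21):
            c = confusion_at_threshold(scores, labels, thr)
            sn = c.tp / (c.tp + c.fn)
            sp = c.tn / (c.tn + c.fp)
            assert sn <= prev_sn + 1e-12
            assert sp >= prev_sp - 1e-12
            prev_sn, prev_sp = sn, sp


@pytest.fixture(scope="module")
def cv_dataset():
    return generate_peptides(
        SyntheticDatasetSpec(500, 500, MotifModel(L=15, seed=21))
    )


class TestCrossValidation:
    def test_five_reports_with_balanced_test_folds(self, cv_dataset):
        report = cross_validate(
            ModelConfig(algorithm="rf", rf_trees=60), {"scheme": "zscale"},
            cv_dataset, k=5, seed=2,
        )
        assert len(report.folds) == 5
        assert report.mean("auc") > 0.8  # planted motif is learnable by RF

    def test_label_shuffle_nulls_auc(self, cv_dataset):
        rng = np.random.default_rng(5)
        from sumosite import LabeledDataset

        shuffled = LabeledDataset(
            cv_dataset.windows, rng.permutation(cv_dataset.labels)
        )
        report = cross_validate(
            ModelConfig(algorithm="rf", rf_trees=60), {"scheme": "zscale"},
            shuffled, k=5, seed=2,
        )
        assert 0.45 <= report.mean("auc") <= 0.55

    def test_fixed_sp_held_on_every_fold(self, cv_dataset):
        # LGBM emits continuous scores; tree-vote ties would quantize the
        # achievable specificities (that pathology is flagged by a warning)
        report = cross_validate(
            ModelConfig(algorithm="lgbm"), {"scheme": "zscale"},
            cv_dataset, k=5, seed=0,
        )
        for fold in report.folds:
            assert fold.sp == pytest.approx(0.650, abs=1 / 100)

    def test_summary_format(self, cv_dataset):
        report = cross_validate(
            ModelConfig(algorithm="rf", rf_trees=40), {"scheme": "zscale"},
            cv_dataset, k=3, seed=0,
        )
        s = report.summary()
        assert set(s) == {"sn", "sp", "mcc", "acc", "auc"}
        assert "±" in s["auc"]


class TestSweep:
    def test_single_setting_sweep_equals_direct_cv(self, cv_dataset):
        cfg = ModelConfig(algorithm="rf", rf_trees=40)
        res = run_sweep("feature", ["zscale"], cv_dataset, cfg, {}, k=3, seed=7)
        direct = cross_validate(cfg, {"scheme": "zscale"}, cv_dataset, k=3, seed=7)
        assert res.reports["zscale"].mean("auc") == pytest.approx(
            direct.mean("auc"), abs=1e-12
        )

    def test_window_length_axis_recuts_windows(self, cv_dataset):
        cfg = ModelConfig(algorithm="rf", rf_trees=30)
        res = run_sweep("window_length", [9, 15], cv_dataset, cfg,
                        {"scheme": "zscale"}, k=2, seed=1)
        assert set(res.reports) == {9, 15}

    def test_invalid_setting_skipped_with_warning(self, cv_dataset):
        cfg = ModelConfig(algorithm="rf", rf_trees=30)
        with pytest.warns(RuntimeWarning, match="skipped"):
            res = run_sweep("window_length", [8, 9], cv_dataset, cfg,
                            {"scheme": "zscale"}, k=2, seed=1)
        assert set(res.reports) == {9}


class TestPairedT:
    def test_identical_folds_give_degenerate_p_one(self):
        assert paired_t_test([0.7] * 5, [0.7] * 5) == (0.0, 1.0)

    def test_known_differences(self):
        a = np.array([0.01, 0.02, 0.03, 0.02, 0.02]) + 0.5
        b = np.full(5, 0.5)
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(6.3246, abs=1e-3)
        assert p == pytest.approx(0.0032, abs=2e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.random(5), rng.random(5)
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_constant_nonzero_difference_flagged(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t, p = paired_t_test([0.8] * 4, [0.7] * 4)
        assert t == np.inf and p == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])
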