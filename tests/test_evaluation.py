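"""Splits, metric identities against independent oracles, kappa, CV wiring."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from wsimil import evaluation as ev
from wsimil import experiments as ex
from wsimil import mil


def random_confusions(rng, n=1000, max_count=40):
    for _ in range(n):
        tp, fp, tn, fn = (int(rng.integers(0, max_count)) for _ in range(4))
        if tp + fp + tn + fn == 0:
            continue
        yield tp, fp, tn, fn


def vectors_from_confusion(tp, fp, tn, fn):
    y_true = np.concatenate([np.ones(tp + fn), np.zeros(tn + fp)])
    y_pred = np.concatenate([np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)])
    return y_true, y_pred


class TestSplits:
    def test_25_patients_default_layout(self):
        splits = ev.make_cv_splits([f"P{i}" for i in range(25)], seed=1)
        assert len(splits) == 5
        for s in splits:
            assert len(s.test_patients) == 5
            assert len(s.val_patients) == 3
            assert len(s.train_patients) == 17

    def test_test_groups_partition_patients(self):
        ids = [f"P{i}" for i in range(25)]
        splits = ev.make_cv_splits(ids, seed=2)
        seen = [p for s in splits for p in s.test_patients]
        assert sorted(seen) == sorted(ids)
        for s in splits:
            assert not set(s.train_patients) & set(s.val_patients)
            assert not set(s.train_patients) & set(s.test_patients)
            assert not set(s.val_patients) & set(s.test_patients)

    def test_same_seed_same_splits(self):
        ids = [f"P{i}" for i in range(25)]
        assert ev.make_cv_splits(ids, seed=3) == ev.make_cv_splits(ids, seed=3)
        assert ev.make_cv_splits(ids, seed=3) != ev.make_cv_splits(ids, seed=4)

    def test_too_few_patients_raise(self):
        with pytest.raises(ValueError):
            ev.make_cv_splits(["a", "b", "c"], n_folds=5, n_val=3)
        with pytest.raises(ValueError):
            ev.make_cv_splits(["a", "a", "b", "c", "d", "e", "f", "g"])


class TestConfusion:
    def test_perfect_predictions(self):
        assert ev.confusion([1, 0, 1], [1, 0, 1]) == (2, 0, 1, 0)

    def test_all_positive_on_half_positive_truth(self):
        y = [1] * 5 + [0] * 5
        tp, fp, tn, fn = ev.confusion(y, [1] * 10)
        assert (tp, fp, tn, fn) == (5, 5, 0, 0)

    def test_swapped_predictions_swap_counts(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        p = rng.integers(0, 2, 30)
        tp, fp, tn, fn = ev.confusion(y, p)
        tp2, fp2, tn2, fn2 = ev.confusion(y, 1 - p)
        assert (tp2, fn2, tn2, fp2) == (fn, tp, fp, tn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = ev.compute_metrics((7, 0, 13, 0), scores=[1] * 7 + [0] * 13, y_true=[1] * 7 + [0] * 13)
        for name in ev.METRICS:
            assert m[name] == pytest.approx(1.0), name

    def test_hand_computed_example(self):
        m = ev.compute_metrics((6, 1, 9, 4))
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["accuracy"] == pytest.approx(15 / 20)
        assert m["balanced_accuracy"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(6 / 7)
        assert m["f1"] == pytest.approx(12 / 17)

    def test_mcc_equals_pearson_of_indicator_vectors(self):
        rng = np.random.default_rng(5)
        checked = 0
        for tp, fp, tn, fn in random_confusions(rng):
            mcc = ev.mcc_from_confusion(tp, fp, tn, fn)
            y_true, y_pred = vectors_from_confusion(tp, fp, tn, fn)
            if mcc is None or np.std(y_pred) == 0:
                continue
            pearson = np.corrcoef(y_true, y_pred)[0, 1]
            assert mcc == pytest.approx(pearson, abs=1e-12)
            checked += 1
        assert checked > 500

    def test_mcc_cross_checked_against_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(6)
        for _ in range(50):
            y = rng.integers(0, 2, 40)
            p = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            ours = ev.mcc_from_confusion(*ev.confusion(y, p))
            assert ours == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_metric_identities_on_random_tables(self):
        rng = np.random.default_rng(7)
        for tp, fp, tn, fn in random_confusions(rng, n=300):
            m = ev.compute_metrics((tp, fp, tn, fn))
            if m["sensitivity"] is not None and m["specificity"] is not None:
                assert m["balanced_accuracy"] == pytest.approx(
                    (m["sensitivity"] + m["specificity"]) / 2
                )
            if m["precision"] not in (None, 0) and m["sensitivity"] not in (None, 0):
                hm = 2 / (1 / m["precision"] + 1 / m["sensitivity"])
                assert m["f1"] == pytest.approx(hm)

    def test_one_class_truth_flags_undefined_not_zero(self):
        m = ev.compute_metrics((5, 0, 0, 2), scores=[1] * 7, y_true=[1] * 7)
        assert m["mcc"] is None
        assert m["auc_roc"] is None
        assert m["specificity"] is None


class TestAUC:
    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for _ in range(50):
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            s = rng.integers(0, 5, 60) / 4.0  # coarse scores with heavy ties
            assert ev.auc_rank(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        assert ev.auc_rank(y, s) == pytest.approx(ev.auc_rank(y, np.exp(3 * s)), abs=1e-12)

    def test_random_scores_on_balanced_truth_near_half(self):
        rng = np.random.default_rng(10)
        n = 2000
        y = np.repeat([0, 1], n // 2)
        s = rng.random(n)
        n1 = n0 = n // 2
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(ev.auc_rank(y, s) - 0.5) <= 3 * se


class TestKappa:
    def test_identical_raters(self):
        res = ev.cohens_kappa([0, 1, 1, 0, 1], [0, 1, 1, 0, 1])
        assert res.kappa == pytest.approx(1.0)

    def test_hand_computable_2x2_example(self):
        """20 both-yes, 60 both-no, 10+10 disagreements: po=0.8, pe=0.58."""
        a = [1] * 20 + [0] * 60 + [1] * 10 + [0] * 10
        b = [1] * 20 + [0] * 60 + [0] * 10 + [1] * 10
        res = ev.cohens_kappa(a, b)
        po, pe = 0.8, 0.3 * 0.3 + 0.7 * 0.7
        assert pe == pytest.approx(0.58)
        assert res.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-9)
        assert res.kappa == pytest.approx(0.5238095238, abs=1e-9)
        lo, hi = res.ci95
        assert lo <= res.kappa <= hi

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        n = 10000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        res = ev.cohens_kappa(a, b)
        se = (res.ci95[1] - res.ci95[0]) / (2 * 1.96)
        assert abs(res.kappa) <= 3 * se

    def test_cross_checked_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(12)
        for _ in range(30):
            a = rng.integers(0, 3, 50)
            b = rng.integers(0, 3, 50)
            res = ev.cohens_kappa(a, b)
            assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            ev.cohens_kappa([1, 0], [1])
        with pytest.raises(ValueError):
            ev.cohens_kappa([], [])


@pytest.fixture(scope="module")
def tiny_cv(tiny_dataset):
    patches, manifest, _ = tiny_dataset
    cfg = dataclasses.replace(ex.desk_cnn_config(seed=5, max_epochs=2), early_stop_patience=2)
    return ev.cross_validate(
        patches, manifest, tasks=("abnormal",), cnn_config=cfg,
        n_folds=2, n_val=1, seed=5,
    )


class TestCrossValidate:
    def test_one_fold_report_per_fold(self, tiny_cv):
        rep = tiny_cv["abnormal"]
        assert [f.fold_index for f in rep.folds] == [1, 2]
        for f in rep.folds:
            assert f.tp + f.fp + f.tn + f.fn == f.n_sections

    def test_each_test_section_scored_exactly_once(self, tiny_cv, tiny_dataset):
        _, manifest, _ = tiny_dataset
        preds = tiny_cv["abnormal"].predictions
        n_no_call = sum(f.n_no_call for f in tiny_cv["abnormal"].folds)
        assert preds["scan_id"].is_unique
        assert len(preds) + n_no_call == len(manifest)

    def test_summary_excludes_undefined_folds(self, tiny_cv):
        rep = tiny_cv["abnormal"]
        for m in ev.METRICS:
            defined = [f.metrics[m] for f in rep.folds if f.metrics[m] is not None]
            assert rep.n_undefined[m] == len(rep.folds) - len(defined)
            if defined:
                assert rep.mean[m] == pytest.approx(np.mean(defined))
                assert rep.sd[m] == pytest.approx(np.std(defined))

    def test_split_hygiene_is_asserted(self):
        splits = [
            ev.CVSplit(1, ("a",), ("b",), ("c",)),
            ev.CVSplit(2, ("c",), ("b",), ("a", "b")),
        ]
        with pytest.raises(AssertionError):
            ev._assert_split_hygiene(splits, ["a", "b", "c"])
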