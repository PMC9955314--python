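import numpy as np
import pytest
from helpers_oracles import count_confusion
from sklearn.metrics import matthews_corrcoef

import tabraster as tr
from tabraster.fusion import ConfusionMatrix, metrics_from_confusion


class TestFuse:
    def test_column_concatenation(self):
        a = np.random.default_rng(0).normal(size=(10, 512))
        b = np.random.default_rng(1).normal(size=(10, 2048))
        f = tr.fuse(a, b)
        assert f.shape == (10, 2560)
        assert np.array_equal(f[:, :512], a)
        assert np.array_equal(f[:, 512:], b)

    def test_zero_column_identity(self):
        a = np.ones((4, 3))
        assert np.array_equal(tr.fuse(a, np.empty((4, 0))), a)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row mismatch"):
            tr.fuse(np.ones((3, 2)), np.ones((4, 2)))


class TestTrainSvm:
    def test_separable_linear_is_perfect(self):
        X = np.array([[0.0, 0.0], [0.1, 0.2], [3.0, 3.1], [3.2, 2.9]])
        y = np.array([0, 0, 1, 1])
        clf = tr.train_svm(X, y, kernel="linear")
        assert (clf.predict(X) == y).all()

    def test_xor_needs_a_nonlinear_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        lin = tr.train_svm(X, y, kernel="linear")
        quad = tr.train_svm(X, y, kernel="quadratic")
        assert (lin.predict(X) == y).mean() <= 0.75
        assert (quad.predict(X) == y).mean() == 1.0

    @pytest.mark.parametrize("kernel", tr.fusion.KERNELS)
    def test_deterministic_predictions(self, kernel):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        p1 = tr.train_svm(X, y, kernel=kernel, seed=0).predict(X)
        p2 = tr.train_svm(X, y, kernel=kernel, seed=0).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            tr.train_svm(np.ones((4, 2)), np.zeros(4, int))

    def test_nonfinite_features_rejected(self):
        X = np.ones((4, 2)); X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            tr.train_svm(X, np.array([0, 0, 1, 1]))

    def test_unknown_kernel(self):
        with pytest.raises(ValueError, match="kernel"):
            tr.train_svm(np.eye(4), np.array([0, 0, 1, 1]), kernel="sigmoid")


class TestEvaluate:
    def test_perfect_predictions(self):
        pred, truth = tr.toy_confusion("perfect", 20, seed=0)
        cm, rep = tr.evaluate(pred, truth)
        assert (cm.fp, cm.fn) == (0, 0)
        assert rep.accuracy == 100.0
        for v in (rep.specificity, rep.precision, rep.sensitivity,
                  rep.f1_score, rep.mcc):
            assert v == 1.0
        assert rep.undefined == ()

    def test_all_positive_predictor(self):
        truth = np.r_[np.ones(50, int), np.zeros(50, int)]
        cm, rep = tr.evaluate(np.ones(100, int), truth)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.accuracy == 50.0
        assert rep.precision == 0.5
        assert rep.f1_score == pytest.approx(2 / 3)
        assert np.isnan(rep.mcc) and "mcc" in rep.undefined

    def test_constructed_confusion_values(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=255, tn=433, fp=67, fn=13))
        assert rep.accuracy == pytest.approx(89.58, abs=5e-3)
        assert rep.sensitivity == pytest.approx(0.9515, abs=5e-5)
        assert rep.specificity == pytest.approx(0.8660, abs=5e-5)

    def test_length_mismatch_and_nonbinary(self):
        with pytest.raises(ValueError, match="length"):
            tr.evaluate([0, 1], [0, 1, 1])
        with pytest.raises(ValueError, match="binary"):
            tr.evaluate([0, 2], [0, 1])

    def test_agrees_with_independent_counting_1000_trials(self):
        """Closed forms vs per-sample counting (and sklearn MCC) on random
        label vectors."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            pred = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            cm, rep = tr.evaluate(pred, truth)
            tp, tn, fp, fn = count_confusion(pred, truth)
            assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
            assert cm.total == n
            assert rep.accuracy == pytest.approx(100 * (tp + tn) / n)
            if not np.isnan(rep.mcc):
                assert rep.mcc == pytest.approx(
                    matthews_corrcoef(truth, pred), abs=1e-10
                )

    def test_mcc_symmetric_under_class_relabeling(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pred = rng.integers(0, 2, 30)
            truth = rng.integers(0, 2, 30)
            _, a = tr.evaluate(pred, truth)
            _, b = tr.evaluate(1 - pred, 1 - truth)
            if not np.isnan(a.mcc) and not np.isnan(b.mcc):
                assert abs(a.mcc) == pytest.approx(abs(b.mcc), abs=1e-12)


def _signal_fixture(seed, n=120, p=40, informative=5):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, p))
    X[:, :informative] += 2.0 * y[:, None]
    return X, y


class TestSelectedFusionClassify:
    def test_classifier_consumes_exactly_n_columns(self):
        X, y = _signal_fixture(0)
        tr_idx, te_idx = np.arange(90), np.arange(90, 120)
        res = tr.selected_fusion_classify(
            X, y, tr_idx, te_idx, n_select=7, kernel="linear", relieff_k=3
        )
        assert res.selected.shape == (7,)
        assert res.classifier.named_steps["scale"].n_features_in_ == 7

    def test_full_selection_matches_plain_svm(self):
        X, y = _signal_fixture(1)
        tr_idx, te_idx = np.arange(90), np.arange(90, 120)
        res = tr.selected_fusion_classify(
            X, y, tr_idx, te_idx, n_select=X.shape[1], kernel="cubic",
            seed=0, relieff_k=3,
        )
        clf = tr.train_svm(X[tr_idx], y[tr_idx], kernel="cubic", seed=0)
        cm, rep = tr.evaluate(clf.predict(X[te_idx]), y[te_idx])
        assert res.report.as_dict() == pytest.approx(rep.as_dict(), nan_ok=True)

    def test_selection_beats_random_columns_paired(self):
        """Columns chosen by ReliefF outperform 5 random columns on average
        (paired over 20 seeds on a 5-informative-column fixture)."""
        sel_acc, rand_acc = [], []
        for seed in range(20):
            X, y = _signal_fixture(seed)
            tr_idx, te_idx = np.arange(90), np.arange(90, 120)
            res = tr.selected_fusion_classify(
                X, y, tr_idx, te_idx, n_select=5, kernel="linear",
                seed=seed, relieff_k=3,
            )
            sel_acc.append(res.report.accuracy)
            cols = np.random.default_rng(seed + 1000).choice(
                X.shape[1], 5, replace=False
            )
            clf = tr.train_svm(X[tr_idx][:, cols], y[tr_idx], kernel="linear",
                               seed=seed)
            _, rep = tr.evaluate(clf.predict(X[te_idx][:, cols]), y[te_idx])
            rand_acc.append(rep.accuracy)
        assert np.mean(sel_acc) >= np.mean(rand_acc)

    def test_selected_indices_reproducible(self):
        X, y = _signal_fixture(2)
        tr_idx, te_idx = np.arange(90), np.arange(90, 120)
        kw = dict(n_select=10, kernel="linear", seed=3, relieff_k=3)
        a = tr.selected_fusion_classify(X, y, tr_idx, te_idx, **kw)
        b = tr.selected_fusion_classify(X, y, tr_idx, te_idx, **kw)
        assert np.array_equal(a.selected, b.selected)

    def test_n_select_out_of_range(self):
        X, y = _signal_fixture(3)
        with pytest.raises(ValueError, match="n_select"):
            tr.selected_fusion_classify(
                X, y, np.arange(90), np.arange(90, 120), n_select=X.shape[1] + 1
            )
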