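"""Feature tables, classifier metrics, SMOTE, and the SVM/RF recipes on
constructed (fast) fixtures; generator-backed staging claims live with the
acceptance checks."""

import numpy as np
import pandas as pd
import pytest

from flysleep.spectra import FREQ_GRID, N_FREQ_BINS, SpectralMatrix
from flysleep.staging import (build_feature_table, classifier_metrics,
                              downsample_balance, feature_columns,
                              mean_report, read_feature_table, smote,
                              train_midsleep_duration_stager,
                              train_probability_stager, train_rf_multiclass,
                              write_feature_table)

CH = tuple(k for k in range(1, 17) if k != 11)


def _sm(fly, labels, rng, bout_ids=None):
    n = len(labels)
    p = rng.normal(size=(n, 15, N_FREQ_BINS))
    return SpectralMatrix(p, FREQ_GRID.copy(), np.array(labels, object),
                          np.array(["mid"] * n, object),
                          np.asarray(bout_ids if bout_ids is not None
                                     else np.zeros(n, int)),
                          CH, fly, 60.0)


def _table(n_per_class=40, classes=("awake", "midsleep"), seed=0,
           shift_cells=None, shift=3.0):
    """Feature table with an optional planted class contrast."""
    rng = np.random.default_rng(seed)
    sms = []
    for fly in range(4):
        labels = [c for c in classes for _ in range(n_per_class // 4)]
        sm = _sm(fly, labels, rng)
        for i, lab in enumerate(labels):
            if lab == classes[0]:
                if shift_cells is None:
                    sm.power_db[i] += shift
                else:
                    sm.power_db[i][shift_cells] += shift
        sms.append(sm)
    return build_feature_table(sms)


class TestMetrics:
    def test_perfect_predictions(self):
        rep = classifier_metrics(["a", "b", "a"], ["a", "b", "a"])
        assert rep.precision == {"a": 1.0, "b": 1.0}
        assert rep.recall == {"a": 1.0, "b": 1.0}
        assert rep.f1 == {"a": 1.0, "b": 1.0}
        assert np.allclose(rep.confusion, np.eye(2))

    def test_recall_from_printed_formula(self):
        # TP=3, FN=1 for class 'a' -> recall 0.75
        y_true = ["a", "a", "a", "a", "b"]
        y_pred = ["a", "a", "a", "b", "b"]
        rep = classifier_metrics(y_true, y_pred)
        assert rep.recall["a"] == pytest.approx(0.75)

    def test_constant_predictor(self):
        y_true = ["a"] * 3 + ["b"] * 7
        rep = classifier_metrics(y_true, ["a"] * 10)
        assert rep.recall["a"] == 1.0
        assert rep.precision["a"] == pytest.approx(0.3)

    def test_matches_sklearn_oracle_to_1e12(self):
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, 200)
        y_pred = rng.choice(classes, 200)
        rep = classifier_metrics(y_true, y_pred, classes=classes)
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred,
                                                     labels=classes,
                                                     zero_division=0)
        for i, c in enumerate(classes):
            assert abs(rep.precision[c] - p[i]) < 1e-12
            assert abs(rep.recall[c] - r[i]) < 1e-12
            assert abs(rep.f1[c] - f[i]) < 1e-12
        assert np.allclose(rep.confusion.sum(axis=1), 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            classifier_metrics(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            classifier_metrics(["a", "a"], ["a", "z"], classes=["a"])


class TestFeatureTable:
    def test_shape_and_order(self):
        rng = np.random.default_rng(0)
        sms = [_sm(0, ["awake"] * 6, rng), _sm(1, ["midsleep"] * 4, rng)]
        t = build_feature_table(sms)
        feats = feature_columns(CH)
        assert len(feats) == 2175
        assert t.shape[0] == 10
        assert list(t.fly_id) == [0] * 6 + [1] * 4
        # channel-major flattening
        assert np.allclose(t[feats].to_numpy()[0],
                           sms[0].power_db[0].ravel())

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = _sm(0, ["awake"] * 3, rng)
        b = _sm(1, ["awake"] * 3, rng)
        b.freq_grid = b.freq_grid + 0.5
        with pytest.raises(ValueError):
            build_feature_table([a, b])

    def test_roundtrip_lossless(self, tmp_path):
        t = _table(n_per_class=8)
        write_feature_table(t, h5_path=tmp_path / "t.h5",
                            csv_path=tmp_path / "t.csv")
        feats = feature_columns(CH)
        th = read_feature_table(h5_path=tmp_path / "t.h5")
        tc = read_feature_table(csv_path=tmp_path / "t.csv")
        assert np.array_equal(th[feats].to_numpy(), t[feats].to_numpy())
        assert np.array_equal(tc[feats].to_numpy(), t[feats].to_numpy())
        assert list(th.label) == list(t.label)


class TestSamplers:
    def test_smote_balances(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(size=(40, 5)), rng.normal(5, 1, size=(10, 5))]
        y = np.array(["a"] * 40 + ["b"] * 10)
        Xb, yb = smote(X, y, seed=1)
        _, counts = np.unique(yb, return_counts=True)
        assert (counts == 40).all()
        # synthetic minority points interpolate within the class range
        newb = Xb[len(y):]
        assert newb.min() >= X[40:].min() - 1e-9
        assert newb.max() <= X[40:].max() + 1e-9

    def test_smote_small_class_rejected(self):
        X = np.zeros((12, 3))
        y = np.array(["a"] * 9 + ["b"] * 3)
        with pytest.raises(ValueError):
            smote(X, y)

    def test_downsample_balances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = np.array(["a"] * 20 + ["b"] * 10)
        Xb, yb = downsample_balance(X, y, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert (counts == 10).all()


class TestProbabilityStager:
    def test_separable_features_perfect(self):
        t = _table(shift=6.0)
        model, rep = train_probability_stager(t, seed=0)
        assert rep.accuracy == 1.0
        assert rep.roc_auc == pytest.approx(1.0)

    def test_permuted_labels_chance(self):
        rng = np.random.default_rng(1)
        t = _table(shift=6.0, n_per_class=60)
        t["label"] = rng.permutation(t["label"].to_numpy())
        _, rep = train_probability_stager(t, seed=0)
        # chance with binomial slack on the held-out rows over 5 splits
        assert abs(rep.accuracy - 0.5) < 0.18

    def test_small_class_rejected(self):
        t = _table(n_per_class=8)
        t = t[~((t.label == "midsleep") & (t.index > 4))]
        with pytest.raises(ValueError):
            train_probability_stager(t, seed=0)

    def test_scaler_fit_on_train_rows_only(self):
        t = _table()
        model, _ = train_probability_stager(t, seed=0)
        scaler, _ = model.pipelines[0]
        n_bal = 2 * min((t.label == c).sum() for c in ("awake", "midsleep"))
        assert int(scaler.n_samples_seen_) == round(0.8 * n_bal)


class TestMidsleepDurationStager:
    def _dur_table(self, with_effect, seed=0):
        rng = np.random.default_rng(seed)
        sms, durs = [], {}
        for fly in range(4):
            labels = ["midsleep"] * 24
            bouts = [i // 12 for i in range(24)]
            sm = _sm(fly, labels, rng, bout_ids=bouts)
            if with_effect:
                for i, b in enumerate(bouts):
                    if b == 0:
                        sm.power_db[i] += 4.0
            sms.append(sm)
            durs[fly] = {0: 8 * 60.0, 1: 20 * 60.0}   # short, long
        return build_feature_table(sms, durs)

    def test_exactly_14_min_is_long(self):
        t = self._dur_table(True)
        t.loc[t.midsleep_min == 20.0, "midsleep_min"] = 14.0
        model, rep = train_midsleep_duration_stager(t, seed=0)
        assert set(model.classes) == {"short_midsleep", "long_midsleep"}

    def test_injected_difference_separable(self):
        t = self._dur_table(True)
        _, rep = train_midsleep_duration_stager(t, seed=0)
        assert rep.accuracy > 0.8

    def test_null_not_separable(self):
        from flysleep.staging import probe_unseen_epochs
        t = self._dur_table(False)
        model, rep = train_midsleep_duration_stager(t, seed=0)
        t_long = t[t.midsleep_min >= 14.0]
        p = model.probability(
            t_long[feature_columns(CH)].to_numpy(float), "short_midsleep")
        assert p.mean() > 0.2        # not confidently 'long' without signal


class TestRF:
    def test_shuffled_labels_importance_near_zero(self):
        rng = np.random.default_rng(2)
        t = _table(n_per_class=24, classes=("a", "b", "c"), shift=0.0)
        res = train_rf_multiclass(t, seed=0, n_iterations=2,
                                  importance_repeats=3)
        s = res.importance.scores
        assert abs(s.mean()) < 0.01
        assert np.abs(s).max() < 0.2
        # and performance is at chance
        assert abs(res.report.accuracy - 1 / 3) < 0.2

    def test_planted_block_concentrates_importance(self):
        block = np.zeros((15, N_FREQ_BINS), bool)
        fmask = (FREQ_GRID >= 5) & (FREQ_GRID < 10)
        block[:3, fmask] = True
        t = _table(n_per_class=32, classes=("a", "b"),
                   shift_cells=block, shift=3.0)
        res = train_rf_multiclass(t, seed=0, n_iterations=2,
                                  importance_repeats=3)
        s = res.importance.scores
        k = int(block.sum())
        top = np.argsort(s.ravel())[::-1][:k]
        assert block.ravel()[top].mean() > 0.5
        assert s[block].mean() > 5 * max(s[~block].mean(), 1e-9)

    def test_smote_placement_flag(self):
        t = _table(n_per_class=24, classes=("a", "b"), shift=4.0)
        r1 = train_rf_multiclass(t, seed=0, n_iterations=1,
                                 compute_importance=False,
                                 smote_before_split=True)
        r2 = train_rf_multiclass(t, seed=0, n_iterations=1,
                                 compute_importance=False,
                                 smote_before_split=False)
        assert r1.report.accuracy >= 0.9 and r2.report.accuracy >= 0.9

    def test_tiny_class_rejected(self):
        t = _table(n_per_class=24, classes=("a", "b"))
        t = t[~((t.label == "b") & (t.groupby("label").cumcount() >= 4))]
        with pytest.raises(ValueError):
            train_rf_multiclass(t, seed=0)


def test_mean_report_averages():
    r1 = classifier_metrics(["a", "b"], ["a", "b"])
    r2 = classifier_metrics(["a", "b"], ["b", "a"])
    m = mean_report([r1, r2])
    assert m.accuracy == pytest.approx(0.5)
    assert m.f1["a"] == pytest.approx(0.5)
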