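"""Metrics, thresholding, LOPO protocol, Taylor statistics, stratification."""

import numpy as np
import pytest

import wallmotion as wm
from wallmotion.evaluation import _fingerprint, variant_configs
from wallmotion.exceptions import ConfigError, DataError
from wallmotion.training import LossConfig, OptimizerParams


class TestPredictLabels:
    def test_strict_threshold(self):
        np.testing.assert_array_equal(
            wm.predict_labels([0.49, 0.51, 0.5]), [0, 1, 0]
        )

    def test_order_preserved(self, rng):
        scores = rng.uniform(size=20)
        np.testing.assert_array_equal(
            wm.predict_labels(scores), (scores > 0.5).astype(int)
        )


class TestClassificationMetrics:
    def test_constant_predictor_on_balanced_labels(self):
        """Support-weighted metrics of an all-TW predictor on balanced labels."""
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = np.zeros(100, dtype=int)
        m = wm.classification_metrics(y_true, y_pred)
        assert m == {"accuracy": 50.0, "precision": 25.0, "recall": 50.0, "f1": 33.33}

    def test_perfect_predictions(self, rng):
        y = rng.integers(0, 2, size=30)
        m = wm.classification_metrics(y, y)
        assert all(v == 100.0 for v in m.values())

    def test_matches_confusion_matrix_oracle(self, rng):
        """Weighted metrics recomputed from a hand-built confusion matrix."""
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        m = wm.classification_metrics(y_true, y_pred)
        tp = {c: np.sum((y_true == c) & (y_pred == c)) for c in (0, 1)}
        support = {c: np.sum(y_true == c) for c in (0, 1)}
        predicted = {c: np.sum(y_pred == c) for c in (0, 1)}
        prec = {c: tp[c] / predicted[c] if predicted[c] else 0.0 for c in (0, 1)}
        rec = {c: tp[c] / support[c] if support[c] else 0.0 for c in (0, 1)}
        f1 = {
            c: 2 * prec[c] * rec[c] / (prec[c] + rec[c]) if prec[c] + rec[c] else 0.0
            for c in (0, 1)
        }
        n = len(y_true)
        w = {c: support[c] / n for c in (0, 1)}
        assert m["accuracy"] == pytest.approx(100 * (tp[0] + tp[1]) / n, abs=0.005)
        assert m["precision"] == pytest.approx(100 * sum(w[c] * prec[c] for c in (0, 1)), abs=0.005)
        assert m["recall"] == pytest.approx(100 * sum(w[c] * rec[c] for c in (0, 1)), abs=0.005)
        assert m["f1"] == pytest.approx(100 * sum(w[c] * f1[c] for c in (0, 1)), abs=0.005)

    def test_accuracy_equals_weighted_recall(self, rng):
        y_true = rng.integers(0, 2, size=97)
        y_pred = rng.integers(0, 2, size=97)
        m = wm.classification_metrics(y_true, y_pred)
        assert m["accuracy"] == m["recall"]

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            wm.classification_metrics([], [])


class TestVariants:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            variant_configs("bogus", wm.ModelConfig(), LossConfig())

    def test_baseline_is_plain_lstm_with_error_loss(self):
        m, l = variant_configs("baseline", wm.ModelConfig(), LossConfig())
        assert m.architecture == "lstm_baseline"
        assert l.weight_patient == 0.0 and l.weight_unlabeled == 0.0
        model = wm.init_model(m)
        assert not any(k.startswith(("conv", "attn")) for k in model.params)
        assert {"dense1_W", "out_W"} <= set(model.params)  # two dense layers

    @pytest.mark.parametrize(
        "variant,patient_on,unlabeled_on",
        [("proposed", True, True), ("only-mae", False, False),
         ("no-patient", False, True), ("no-unlabeled", True, False)],
    )
    def test_variant_loss_weights(self, variant, patient_on, unlabeled_on):
        base = LossConfig()
        _, l = variant_configs(variant, wm.ModelConfig(), base)
        assert l.weight_patient == (base.weight_patient if patient_on else 0.0)
        assert l.weight_unlabeled == (base.weight_unlabeled if unlabeled_on else 0.0)


@pytest.fixture(scope="module")
def lopo_result(small_cohort):
    _, trajs = small_cohort
    mcfg = wm.ModelConfig(conv_filters=4, lstm_units=6, attention_dim=3,
                          embedding_dim=4)
    opt = OptimizerParams(steps_per_epoch=4, early_stopping=False)
    folds, summary = wm.lopo_cross_validate(
        trajs, "proposed", mcfg, LossConfig(batch_size=6), opt, epochs=2, seed=0
    )
    return trajs, folds, summary


class TestLopoProtocol:
    def test_one_fold_per_patient(self, lopo_result):
        trajs, folds, _ = lopo_result
        assert sorted(f.patient_id for f in folds) == ["patient000", "patient001"]

    def test_every_labeled_point_scored_once(self, lopo_result):
        trajs, folds, _ = lopo_result
        for f in folds:
            n_labeled = sum(
                1 for t in trajs if t.patient_id == f.patient_id and t.label != -1
            )
            assert len(f.scores) == n_labeled == len(f.y_true)

    def test_fold_isolation(self, lopo_result):
        """Training fingerprint of each fold excludes the held-out patient."""
        trajs, folds, _ = lopo_result
        patients = sorted({t.patient_id for t in trajs})
        for f in folds:
            others = [p for p in patients if p != f.patient_id]
            assert f.train_fingerprint == _fingerprint(others)
            assert f.train_fingerprint != _fingerprint(patients)

    def test_summary_is_mean_of_fold_metrics(self, lopo_result):
        _, folds, summary = lopo_result
        for m in wm.METRIC_NAMES:
            assert summary[m] == pytest.approx(
                np.mean([f.metrics[m] for f in folds]), abs=1e-12
            )

    def test_metrics_recomputable_from_stored_predictions(self, lopo_result):
        _, folds, _ = lopo_result
        for f in folds:
            assert wm.classification_metrics(f.y_true, f.y_pred) == f.metrics

    def test_single_patient_rejected(self, small_cohort):
        _, trajs = small_cohort
        one = [t for t in trajs if t.patient_id == "patient000"]
        with pytest.raises(DataError):
            wm.lopo_cross_validate(one, "proposed", epochs=1, seed=0)


class TestRunAblation:
    def test_rows_and_identical_partitions(self, small_cohort):
        _, trajs = small_cohort
        mcfg = wm.ModelConfig(conv_filters=3, lstm_units=4, attention_dim=2,
                              embedding_dim=3)
        opt = OptimizerParams(steps_per_epoch=3, early_stopping=False)
        table, folds = wm.run_ablation(
            trajs, variants=("only-mae", "proposed"), model_config=mcfg,
            loss_config=LossConfig(batch_size=6), optimizer_params=opt,
            epochs=1, seed=4,
        )
        assert list(table.index) == ["only-mae", "proposed"]
        assert list(table.columns) == list(wm.METRIC_NAMES)
        a = [f.patient_id for f in folds["only-mae"]]
        b = [f.patient_id for f in folds["proposed"]]
        assert a == b
        for fa, fb in zip(folds["only-mae"], folds["proposed"]):
            assert fa.train_fingerprint == fb.train_fingerprint

    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(ConfigError):
            wm.run_ablation(small_cohort[1], variants=("proposed", "nope"))


class TestTaylorStatistics:
    def test_identity_case(self):
        labels = np.array([0, 1, 0, 1, 1], dtype=float)
        ts = wm.taylor_statistics(labels, labels)
        assert ts.pearson_r == pytest.approx(1.0)
        assert ts.centered_rmse == pytest.approx(0.0, abs=1e-12)
        assert ts.sd_model == pytest.approx(ts.sd_reference)

    def test_anticorrelated_case(self):
        labels = np.array([0, 1, 0, 1], dtype=float)
        ts = wm.taylor_statistics(1 - labels, labels)
        assert ts.pearson_r == pytest.approx(-1.0)

    def test_law_of_cosines_identity(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50).astype(float)
        ts = wm.taylor_statistics(scores, labels)
        lhs = ts.centered_rmse**2
        rhs = (
            ts.sd_model**2 + ts.sd_reference**2
            - 2 * ts.sd_model * ts.sd_reference * ts.pearson_r
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_constant_reference_rejected(self):
        with pytest.raises(DataError):
            wm.taylor_statistics([0.1, 0.9], [1, 1])


class TestStratifyPatients:
    @staticmethod
    def _fold(pid, acc):
        metrics = {"accuracy": acc, "precision": acc, "recall": acc, "f1": acc}
        return wm.FoldResult(pid, np.array([]), np.array([]), np.array([]), None, metrics)

    def test_boundary_at_cutoff(self):
        out = wm.stratify_patients([self._fold("a", 79.9), self._fold("b", 80.1)])
        assert out["failed"] == ["a"] and out["succeeded"] == ["b"]

    def test_all_succeed_gives_empty_failed_set(self):
        out = wm.stratify_patients([self._fold("a", 95.0), self._fold("b", 99.0)])
        assert out["failed"] == []
        assert np.isnan(out["failed_metrics"]["f1"])

    def test_stratified_means_recompute(self, rng):
        accs = rng.uniform(50, 100, size=9)
        folds = [self._fold(f"p{i}", a) for i, a in enumerate(accs)]
        out = wm.stratify_patients(folds, cutoff=80.0)
        failed = accs[accs < 80.0]
        if len(failed):
            assert out["failed_metrics"]["accuracy"] == pytest.approx(failed.mean())
        succeeded = accs[accs >= 80.0]
        assert out["succeeded_metrics"]["accuracy"] == pytest.approx(succeeded.mean())
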