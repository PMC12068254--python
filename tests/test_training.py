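"""Composite loss terms, ablation algebra, gradients, and the training loop."""

import numpy as np
import pytest

import wallmotion as wm
from wallmotion.autodiff import Tensor
from wallmotion.exceptions import ConfigError, DataError
from wallmotion.model import forward_graph
from wallmotion.training import (
    LossConfig,
    OptimizerParams,
    composite_loss_graph,
    train_model,
)


class TestErrorTerm:
    def test_perfect_predictions_zero(self):
        assert wm.error_term([0.0, 1.0], [0, 1], "mae") == 0.0
        assert wm.error_term([0.0, 1.0], [0, 1], "mse") == 0.0

    def test_hand_arithmetic(self):
        assert wm.error_term([0.5, 0.5], [0, 1], "mae") == pytest.approx(0.5)
        assert wm.error_term([0.25, 0.75], [0, 1], "mse") == pytest.approx(0.0625)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            wm.error_term([0.5], [0, 1], "mae")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            wm.error_term([0.5], [0], "rmse")


class TestPatientInvarianceTerm:
    def test_single_patient_is_zero(self, rng):
        emb = rng.normal(size=(4, 3))
        assert wm.patient_invariance_term(emb, [0, 0, 1, 1], ["a"] * 4) == 0.0

    def test_three_four_five(self):
        emb = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert wm.patient_invariance_term(emb, [0, 0], ["a", "b"]) == pytest.approx(5.0)

    def test_matches_brute_force_pair_enumeration(self, rng):
        emb = rng.normal(size=(12, 5))
        labels = rng.integers(0, 2, size=12)
        patients = rng.choice(["a", "b", "c"], size=12)
        dists = [
            np.linalg.norm(emb[i] - emb[j])
            for i in range(12)
            for j in range(i + 1, 12)
            if labels[i] == labels[j] and patients[i] != patients[j]
        ]
        expect = np.mean(dists) if dists else 0.0
        assert wm.patient_invariance_term(emb, labels, patients) == pytest.approx(
            expect, rel=1e-9
        )

    def test_symmetry_under_patient_permutation_and_label_swap(self, rng):
        emb = rng.normal(size=(10, 4))
        labels = rng.integers(0, 2, size=10)
        patients = rng.choice(["a", "b", "c"], size=10)
        base = wm.patient_invariance_term(emb, labels, patients)
        relabel = {"a": "c", "b": "a", "c": "b"}
        assert wm.patient_invariance_term(
            emb, 1 - labels, [relabel[p] for p in patients]
        ) == pytest.approx(base, rel=1e-12)


class TestUnlabeledSeparationTerm:
    def test_empty_set_is_zero(self, rng):
        assert wm.unlabeled_separation_term(rng.normal(size=(3, 2)), np.empty((0, 2))) == 0.0

    def test_below_margin_is_distance(self):
        assert wm.unlabeled_separation_term([[0.0, 0.0]], [[3.0, 4.0]], 10.0) == pytest.approx(5.0)

    def test_margin_caps_distance(self):
        assert wm.unlabeled_separation_term([[0.0, 0.0]], [[3.0, 4.0]], 2.0) == pytest.approx(2.0)

    def test_negative_margin_rejected(self):
        with pytest.raises(ConfigError):
            wm.unlabeled_separation_term([[0.0]], [[1.0]], -1.0)

    def test_monotone_in_margin(self, rng):
        lab = rng.normal(size=(5, 3))
        unl = rng.normal(size=(4, 3))
        values = [
            wm.unlabeled_separation_term(lab, unl, m)
            for m in [0.0, 0.5, 1.0, 2.0, 5.0, np.inf]
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        max_d = max(
            np.linalg.norm(a - b) for a in lab for b in unl
        )
        assert wm.unlabeled_separation_term(lab, unl, max_d + 1) == pytest.approx(
            wm.unlabeled_separation_term(lab, unl, np.inf)
        )


class TestCompositeLoss:
    def test_all_terms_vanish_for_perfect_single_patient_batch(self, rng):
        emb = rng.normal(size=(3, 4))
        total, parts = wm.composite_loss(
            [0.0, 1.0, 1.0], [0, 1, 1], emb, ["a", "a", "a"]
        )
        assert total == 0.0
        assert parts["patient"] == 0.0 and parts["unlabeled"] == 0.0

    def test_hand_built_batch(self):
        """2 patients x 1 TW each + 1 unlabeled point, 2-d embeddings."""
        preds = np.array([0.2, 0.4])
        labels = np.array([0, 0])
        emb = np.array([[0.0, 0.0], [3.0, 4.0]])
        unl = np.array([[6.0, 8.0]])
        cfg = LossConfig(error_term="mae", margin=10.0, normalize_embeddings=False,
                         weight_patient=1.0, weight_unlabeled=1.0)
        total, parts = wm.composite_loss(preds, labels, emb, ["a", "b"], unl, cfg)
        # by hand: error = 0.3; L_p = 5; L_m = mean(10, 5) = 7.5
        assert parts["error"] == pytest.approx(0.3)
        assert parts["patient"] == pytest.approx(5.0)
        assert parts["unlabeled"] == pytest.approx(7.5, rel=1e-6)
        assert total == pytest.approx(0.3 + 5.0 - 7.5, rel=1e-6)

    def test_zeroed_weights_reproduce_plain_error_bitwise(self, rng):
        """Ablation algebra: (1,0,0) weights equal the error term exactly."""
        preds = rng.uniform(size=6)
        labels = rng.integers(0, 2, size=6)
        emb = rng.normal(size=(6, 4))
        pats = rng.choice(["a", "b"], size=6)
        unl = rng.normal(size=(3, 4))
        cfg = LossConfig(weight_patient=0.0, weight_unlabeled=0.0)
        total, _ = wm.composite_loss(preds, labels, emb, pats, unl, cfg)
        assert total == wm.error_term(preds, labels, "mae")

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_hand_enumerated_pair_sums(self, trial, rng):
        """Full composite value equals an independent pair-loop computation."""
        n_l, n_u = int(rng.integers(2, 8)), int(rng.integers(0, 5))
        preds = rng.uniform(size=n_l)
        labels = rng.integers(0, 2, size=n_l)
        emb = rng.normal(size=(n_l, 3))
        pats = rng.choice(["a", "b", "c"], size=n_l)
        unl = rng.normal(size=(n_u, 3))
        w_e, w_p, w_u = rng.uniform(0.1, 2.0, size=3)
        m = float(rng.uniform(0.5, 4.0))
        cfg = LossConfig(
            error_term="mse", weight_error=w_e, weight_patient=w_p,
            weight_unlabeled=w_u, margin=m, normalize_embeddings=False,
        )
        total, _ = wm.composite_loss(preds, labels, emb, pats, unl, cfg)

        err = np.mean((labels - preds) ** 2)
        pair_d = [
            np.linalg.norm(emb[i] - emb[j])
            for i in range(n_l) for j in range(i + 1, n_l)
            if labels[i] == labels[j] and pats[i] != pats[j]
        ]
        lp = np.mean(pair_d) if pair_d else 0.0
        lm = (
            np.mean([min(np.linalg.norm(e - u), m) for e in emb for u in unl])
            if n_u else 0.0
        )
        assert total == pytest.approx(w_e * err + w_p * lp - w_u * lm, rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        """End-to-end loss gradient agrees with central differences to 1e-4."""
        X = rng.normal(size=(5, 5, 10))
        y = np.array([0, 1, 0])
        pats = np.array(["a", "b", "a"])
        cfg = wm.ModelConfig(conv_filters=3, lstm_units=4, attention_dim=3,
                             embedding_dim=4, seed=1)
        lcfg = LossConfig(weight_patient=0.7, weight_unlabeled=0.5, margin=2.0)
        model = wm.init_model(cfg)

        def loss():
            s, e, _ = forward_graph(model, X)
            total, _ = composite_loss_graph(s[:3], y, e[:3], pats, e[3:], lcfg)
            return total

        out = loss()
        out.backward()
        grads = {k: v.grad.copy() for k, v in model.params.items()}
        eps, worst = 1e-6, 0.0
        for name, p in model.params.items():
            flat = p.data.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                up = float(loss().data)
                flat[i] = old - eps
                lo = float(loss().data)
                flat[i] = old
                fd = (up - lo) / (2 * eps)
                an = grads[name].ravel()[i]
                worst = max(worst, abs(fd - an) / max(abs(fd), abs(an), 1e-8))
        assert worst < 1e-4, worst


class TestTrainModel:
    def test_epochs_zero_returns_initialized_model(self, small_cohort):
        _, trajs = small_cohort
        cfg = wm.ModelConfig(conv_filters=4, lstm_units=4, attention_dim=3,
                             embedding_dim=4, seed=5)
        model, history = train_model(trajs, model_config=cfg, epochs=0, seed=0)
        init = wm.init_model(cfg)
        for k in init.params:
            np.testing.assert_array_equal(model.params[k].data, init.params[k].data)
        assert history.empty
        assert model.norm_stats is not None

    def test_training_reduces_error_term(self, small_cohort):
        _, trajs = small_cohort
        cfg = wm.ModelConfig(conv_filters=8, lstm_units=8, attention_dim=4,
                             embedding_dim=8, seed=2)
        opt = OptimizerParams(steps_per_epoch=10, early_stopping=False)
        model, history = train_model(
            trajs, model_config=cfg, loss_config=LossConfig(batch_size=8),
            optimizer_params=opt, epochs=6, seed=1,
        )
        assert history["error"].iloc[-1] < history["error"].iloc[0]

    def test_empty_labeled_set_rejected(self):
        params = wm.WallMotionParams()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, trajs = wm.simulate_cohort(1, {"TW": 0, "HR": 0, "unlabeled": 4}, params, seed=0)
        with pytest.raises(DataError):
            train_model(trajs, epochs=1, seed=0)

    def test_reproducible_given_seed(self, small_cohort):
        _, trajs = small_cohort
        cfg = wm.ModelConfig(conv_filters=4, lstm_units=4, attention_dim=3,
                             embedding_dim=4, seed=8)
        opt = OptimizerParams(steps_per_epoch=4, early_stopping=False)
        kw = dict(model_config=cfg, loss_config=LossConfig(batch_size=6),
                  optimizer_params=opt, epochs=2, seed=13)
        m1, h1 = train_model(small_cohort[1], **kw)
        m2, h2 = train_model(small_cohort[1], **kw)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)
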