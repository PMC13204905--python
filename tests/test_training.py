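"""Training-loop components: class weights, weighted cross-entropy,
weighted sampling, layer-wise learning rates, SGDR schedule, gradient
clipping, early stopping, and the optimizer against a hand-stepped oracle."""

import math

import numpy as np
import pytest

import rtafnet as rt
from rtafnet.nn.layers import Param
from rtafnet.nn.model import RTAFNet
from rtafnet.nn.optim import AdamW, clip_gradients, global_grad_norm
from rtafnet.training import (
    CLASSES, TrainConfig, early_stopper, labels_to_index,
    layerwise_param_groups, make_class_weights, make_sampler, sgdr_lr,
    wce_loss,
)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        w = make_class_weights(["AF"] * 50 + ["NonAF"] * 50)
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_inverse_frequency_formula(self):
        # 90 NonAF / 10 AF: w = N/(C*N_c) = (0.5556, 5.0)
        w = make_class_weights(["NonAF"] * 90 + ["AF"] * 10)
        assert w[CLASSES.index("NonAF")] == pytest.approx(100 / (2 * 90))
        assert w[CLASSES.index("AF")] == pytest.approx(5.0)

    def test_weights_satisfy_total_identity(self):
        labels = ["AF"] * 13 + ["NonAF"] * 87
        w = make_class_weights(labels)
        y = labels_to_index(labels)
        counts = np.bincount(y)
        assert float((w * counts).sum()) == pytest.approx(len(labels))

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            make_class_weights(["AF"] * 5)


class TestWceLoss:
    def test_perfect_prediction_zero_loss(self):
        logits = np.array([[100.0, 0.0], [0.0, 100.0]])
        loss, _ = wce_loss(logits, np.array([0, 1]), np.ones(2))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_weighted_case(self):
        # w=(1,2), true class 2, probabilities (0.5, 0.5): loss = 2 ln 2
        logits = np.array([[0.3, 0.3]])
        loss, _ = wce_loss(logits, np.array([1]), np.array([1.0, 2.0]))
        assert loss == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_uniform_weights_equal_cross_entropy(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, size=40)
        loss, _ = wce_loss(logits, y, np.ones(2))
        # naive per-sample cross-entropy oracle
        ce = 0.0
        for i in range(40):
            p = np.exp(logits[i]) / np.exp(logits[i]).sum()
            ce -= math.log(p[y[i]])
        assert loss == pytest.approx(ce / 40, abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 2))
        y = np.array([0, 1, 1, 0, 1])
        w = np.array([0.7, 1.8])
        _, g = wce_loss(logits, y, w)
        eps = 1e-6
        for i in range(5):
            for j in range(2):
                up = logits.copy(); up[i, j] += eps
                dn = logits.copy(); dn[i, j] -= eps
                fd = (wce_loss(up, y, w)[0] - wce_loss(dn, y, w)[0]) / (2 * eps)
                assert g[i, j] == pytest.approx(fd, abs=1e-6)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            wce_loss(np.array([[np.inf, 0.0]]), np.array([0]), np.ones(2))


class TestSampler:
    def test_balanced_labels_uniform(self):
        w = make_sampler(["AF"] * 10 + ["NonAF"] * 10)
        np.testing.assert_allclose(w, 1 / 20)

    def test_minority_nine_times_weight_and_balanced_draws(self):
        labels = ["NonAF"] * 900 + ["AF"] * 100
        w = make_sampler(labels)
        assert w[-1] / w[0] == pytest.approx(9.0)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(labels), size=100_000, p=w)
        frac_af = np.mean(draws >= 900)
        assert frac_af == pytest.approx(0.5, abs=0.02)


class TestParamGroups:
    @pytest.fixture(scope="class")
    def model(self, tiny_model_config):
        return RTAFNet(tiny_model_config, init_seed=0)

    def test_groups_partition_all_parameters(self, model):
        groups = layerwise_param_groups(model, TrainConfig())
        ids = [id(p) for g in groups.values() for p in g["params"]]
        assert len(ids) == len(set(ids)) == len(model.parameters())

    def test_group_learning_rates(self, model):
        cfg = TrainConfig(base_lr=5e-4)
        opt = AdamW(layerwise_param_groups(model, cfg), base_lr=cfg.base_lr)
        lrs = opt.group_lrs()
        assert lrs["backbone"] == pytest.approx(5e-4)
        assert lrs["attention"] == pytest.approx(7.5e-4)
        assert lrs["classifier"] == pytest.approx(1e-3)

    def test_encoder_parameters_in_attention_group(self, model):
        groups = layerwise_param_groups(model, TrainConfig())
        att_names = {p.name for p in groups["attention"]["params"]}
        assert any(n.startswith("enc") for n in att_names)
        assert any("attnblk" in n for n in att_names)

    def test_untagged_role_rejected(self, model):
        cfg = TrainConfig(lr_multipliers={"backbone": 1.0})
        with pytest.raises(ValueError, match="role"):
            layerwise_param_groups(model, cfg)


class TestSgdr:
    def test_start_factor_one(self):
        assert sgdr_lr(0, TrainConfig()) == pytest.approx(1.0)

    def test_mid_cycle_half(self):
        cfg = TrainConfig(sgdr_t0=10, sgdr_min_lr=0.0)
        assert sgdr_lr(5, cfg) == pytest.approx(0.5)

    def test_restart_returns_to_one(self):
        cfg = TrainConfig(sgdr_t0=10, sgdr_t_mult=2)
        assert sgdr_lr(10, cfg) == pytest.approx(1.0)
        assert sgdr_lr(30, cfg) == pytest.approx(1.0)  # second restart at 10+20

    def test_floor_at_min_lr(self):
        cfg = TrainConfig(sgdr_t0=10, sgdr_min_lr=1e-5, base_lr=1e-3)
        # just before the restart the factor approaches min_lr / base_lr
        assert sgdr_lr(9.999, cfg) >= 1e-5 / 1e-3


class TestClipping:
    def _params(self, values):
        ps = []
        for i, v in enumerate(values):
            p = Param(np.zeros_like(np.asarray(v, float)), f"p{i}", "backbone")
            p.grad = np.asarray(v, float)
            ps.append(p)
        return ps

    def test_small_gradients_unchanged(self):
        ps = self._params([[0.3, 0.4]])
        clip_gradients(ps, 1.0)
        np.testing.assert_allclose(ps[0].grad, [0.3, 0.4])

    def test_large_gradients_scaled_to_norm(self):
        ps = self._params([[6.0], [8.0]])  # norm 10
        pre = clip_gradients(ps, 1.0)
        assert pre == pytest.approx(10.0)
        assert global_grad_norm(ps) == pytest.approx(1.0)
        # direction preserved
        assert ps[0].grad[0] / ps[1].grad[0] == pytest.approx(6 / 8)


class TestEarlyStopper:
    def test_rule_application(self):
        es = early_stopper(2)
        stops = [es.update(f, i) for i, f in enumerate([0.5, 0.6, 0.55, 0.58])]
        assert stops == [False, False, False, True]
        assert es.best_epoch == 1

    def test_monotone_improvement_never_stops(self):
        es = early_stopper(1)
        assert not any(es.update(f, i) for i, f in enumerate(np.linspace(0.1, 0.9, 20)))

    def test_equality_counts_as_non_improvement(self):
        es = early_stopper(1)
        assert not es.update(0.7, 0)
        assert es.update(0.7, 1)
        assert es.best_epoch == 0


class TestAdamWOracle:
    def test_single_step_matches_hand_computation(self):
        # 2-parameter model, one AdamW step stepped by hand
        p = Param(np.array([1.0, -2.0]), "w", "backbone", decay=True)
        p.grad = np.array([0.5, -1.0])
        opt = AdamW({"backbone": {"params": [p], "lr_mult": 1.0}},
                    base_lr=0.1, weight_decay=0.01)
        opt.step()
        g = np.array([0.5, -1.0])
        m = 0.1 * g
        v = 0.001 * g * g
        mhat = m / 0.1
        vhat = v / 0.001
        expected = np.array([1.0, -2.0])
        expected -= 0.1 * 0.01 * expected          # decoupled weight decay
        expected -= 0.1 * mhat / (np.sqrt(vhat) + 1e-8)
        np.testing.assert_allclose(p.data, expected, atol=1e-12)

    def test_decay_skipped_for_flagged_parameters(self):
        p = Param(np.array([10.0]), "bn.gamma", "backbone", decay=False)
        p.grad = np.array([0.0])
        opt = AdamW({"backbone": {"params": [p], "lr_mult": 1.0}},
                    base_lr=0.1, weight_decay=0.5)
        opt.step()
        assert p.data[0] == pytest.approx(10.0)


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def trained(self, small_splits):
        cfg = rt.scaled_down_model_config()
        tc = TrainConfig(max_epochs=4, patience=4, batch_size=32, seed=11)
        clf = rt.AFNetClassifier(small_splits, model_config=cfg,
                                 train_config=tc, init_seed=3)
        return clf.fit(), tc

    def test_history_is_consistent(self, trained):
        res, tc = trained
        h = res.history
        assert h.n_epochs <= tc.max_epochs
        assert len(h.val_f1) == h.n_epochs
        assert h.best_epoch == int(np.argmax(h.val_f1))

    def test_loss_decreases_early(self, trained):
        res, _ = trained
        assert res.history.train_loss[-1] < res.history.train_loss[0]

    def test_lr_trace_equals_multiplier_times_schedule(self, trained):
        res, tc = trained
        for epoch, lrs in enumerate(res.history.lrs):
            factor = sgdr_lr(epoch, tc)
            for role, mult in tc.lr_multipliers.items():
                assert lrs[role] == pytest.approx(tc.base_lr * mult * factor)

    def test_same_seed_identical_history(self, small_splits):
        cfg = rt.scaled_down_model_config()
        tc = TrainConfig(max_epochs=2, patience=2, batch_size=32, seed=21)
        runs = []
        for _ in range(2):
            clf = rt.AFNetClassifier(small_splits, model_config=cfg,
                                     train_config=tc, init_seed=5)
            runs.append(clf.fit().history)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_f1 == runs[1].val_f1
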