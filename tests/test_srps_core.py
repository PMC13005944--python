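"""Classifier, losses, policy gradient, training loop, and ablations."""

import numpy as np
import pytest

from srps.srps_core import (
    SrpsConfig,
    SrpsModel,
    advantage,
    baseline_loss,
    episode_reward,
    load_model,
    predict_proba,
    predict_subtype,
    reinforce_loss,
    replace_cfg,
    sample_subtypes,
    save_model,
    soft_delta_rmst,
    supervised_loss,
    train,
    train_soft_ablation,
    _SoftKMContext,
    _init_model,
)
from srps._nn import softmax
from srps.survival_stats import km_curve, rmst, RmstConfig


def model_with_theta(theta):
    cfg = SrpsConfig(k=theta.shape[0], d=theta.shape[1], use_baseline=False)
    m = _init_model(cfg, np.random.default_rng(0))
    m.theta = np.asarray(theta, dtype=float)
    return m


class TestPredict:
    def test_zero_weights_give_uniform_rows(self, rng):
        m = model_with_theta(np.zeros((3, 4)))
        p = predict_proba(m, rng.normal(size=(5, 4)))
        np.testing.assert_allclose(p, 1 / 3)

    def test_closed_form_two_class(self):
        # logits (ln 3, 0) -> probabilities (0.75, 0.25)
        m = model_with_theta(np.array([[np.log(3.0)], [0.0]]))
        p = predict_proba(m, np.ones((1, 1)))
        np.testing.assert_allclose(p, [[0.75, 0.25]], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        m = model_with_theta(rng.normal(size=(4, 6)))
        p = predict_proba(m, rng.normal(size=(20, 6)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_argmax_and_tie_rule(self, rng):
        m = model_with_theta(np.zeros((2, 3)))
        # exact tie -> smaller subtype index
        assert (predict_subtype(m, rng.normal(size=(4, 3))) == 1).all()
        m2 = model_with_theta(rng.normal(size=(3, 5)))
        x = rng.normal(size=(30, 5))
        np.testing.assert_array_equal(
            predict_subtype(m2, x), np.argmax(x @ m2.theta.T, axis=1) + 1)

    def test_dimension_mismatch_rejected(self, rng):
        m = model_with_theta(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            predict_proba(m, rng.normal(size=(4, 5)))


class TestSampling:
    def test_degenerate_distribution(self, rng):
        p = np.tile([1.0, 0.0], (50, 1))
        y = sample_subtypes(p, rng)
        assert (y[:, 0] == 1).all()

    def test_frequency_matches_probability(self):
        rng = np.random.default_rng(7)
        p = np.tile([0.5, 0.5], (10_000, 1))
        y = sample_subtypes(p, rng)
        assert y[:, 0].mean() == pytest.approx(0.5, abs=0.02)

    def test_seeded_reproducibility(self):
        p = np.tile([0.3, 0.7], (100, 1))
        a = sample_subtypes(p, np.random.default_rng(3))
        b = sample_subtypes(p, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_invalid_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_subtypes(np.array([[0.5, 0.4]]), rng)


class TestLosses:
    def test_supervised_exact_fit_is_zero(self):
        y = np.eye(3)
        assert supervised_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_supervised_closed_form(self):
        p = np.array([[0.5, 0.5]])
        y = np.array([[1.0, 0.0]])
        assert supervised_loss(p, y) == pytest.approx(np.log(2))

    def test_supervised_decreases_toward_truth(self):
        y = np.array([[1.0, 0.0]])
        losses = [supervised_loss(np.array([[q, 1 - q]]), y) for q in (0.3, 0.6, 0.9)]
        assert losses[0] > losses[1] > losses[2]

    def test_advantage_and_no_baseline_ablation(self, rng):
        assert advantage(10.0, np.array([3.0]), 2.0)[0] == pytest.approx(5.0)
        q = advantage(4.2, np.zeros(7), 0.0)
        np.testing.assert_allclose(q, 4.2)  # q = r without a baseline
        perfect = advantage(4.2, np.full(7, 4.2), 0.0)
        np.testing.assert_allclose(perfect, 0.0)

    def test_baseline_loss_is_l2_norm(self):
        assert baseline_loss(4.0, np.array([1.0]), 1.0) == pytest.approx(2.0)
        assert baseline_loss(1.0, np.array([0.5, 0.5]), 0.5) == pytest.approx(0.0)

    def test_reinforce_zero_advantage_zero_loss(self, rng):
        p = softmax(rng.normal(size=(6, 3)))
        yhat = np.eye(3)[rng.integers(0, 3, 6)]
        assert reinforce_loss(p, yhat, np.zeros(6)) == 0.0

    def test_reinforce_closed_form(self):
        p = np.array([[0.5, 0.5]])
        yhat = np.array([[1.0, 0.0]])
        assert reinforce_loss(p, yhat, np.array([1.0])) == pytest.approx(np.log(2))

    def test_policy_gradient_matches_finite_differences(self, rng):
        """Analytic d l_RE / d Theta vs central differences on a frozen batch."""
        n, d, k = 12, 4, 3
        x = rng.normal(size=(n, d))
        theta = rng.normal(size=(k, d)) * 0.5
        yhat = np.eye(k)[rng.integers(0, k, n)]
        q = rng.normal(size=n)  # includes negative advantages

        def loss_at(th):
            return reinforce_loss(softmax(x @ th.T), yhat, q)

        p = softmax(x @ theta.T)
        analytic = ((q[:, None] * (p - yhat)) / n).T @ x
        eps = 1e-6
        for a in range(k):
            for b in range(d):
                tp, tm = theta.copy(), theta.copy()
                tp[a, b] += eps
                tm[a, b] -= eps
                fd = (loss_at(tp) - loss_at(tm)) / (2 * eps)
                assert analytic[a, b] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestEpisodeReward:
    def test_clean_two_group_gap(self):
        cfg = SrpsConfig(k=2, d=1)
        yhat = np.eye(2)[np.array([0] * 5 + [1] * 5)]
        times = np.array([70.0] * 5 + [10.0] * 5)
        events = np.array([0] * 5 + [1] * 5)
        assert episode_reward(yhat, times, events, cfg) == pytest.approx(50.0)

    def test_empty_group_penalty(self):
        cfg = SrpsConfig(k=2, d=1)
        yhat = np.eye(2)[np.zeros(6, dtype=int)]
        r = episode_reward(yhat, np.arange(1.0, 7.0), np.ones(6), cfg)
        assert r == -cfg.t_restrict

    def test_swap_negates_two_group_reward(self, rng):
        cfg = SrpsConfig(k=2, d=1)
        g = rng.integers(0, 2, 30)
        times = rng.uniform(1, 80, 30)
        events = np.ones(30)
        r1 = episode_reward(np.eye(2)[g], times, events, cfg)
        r2 = episode_reward(np.eye(2)[1 - g], times, events, cfg)
        assert r1 == pytest.approx(-r2)

    def test_true_labels_beat_any_label_permutation_small_n(self):
        """With unswapped survival, the threshold grouping under the correct
        group indexing beats every permutation of the group labels (brute
        force on 8 subjects)."""
        cfg = SrpsConfig(k=2, d=1)
        times = np.array([50.0, 45.0, 40.0, 35.0, 25.0, 20.0, 10.0, 5.0])
        events = np.ones(8)
        truth = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        r_truth = episode_reward(np.eye(2)[truth], times, events, cfg)
        r_swapped = episode_reward(np.eye(2)[1 - truth], times, events, cfg)
        assert r_truth > 0 > r_swapped
        assert r_truth >= r_swapped


class TestSoftRelaxation:
    def test_one_hot_equals_hard(self, rng):
        n, k = 25, 3
        times = rng.uniform(1, 80, n)
        events = (rng.random(n) < 0.7).astype(float)
        g = rng.integers(0, k, n)
        yhat = np.eye(k)[g]
        cfg = SrpsConfig(k=k, d=1)
        hard = episode_reward(yhat, times, events, cfg)
        soft = soft_delta_rmst(yhat, times, events, 60.0)
        assert soft == pytest.approx(hard, abs=1e-6)

    def test_uniform_weights_zero_gap(self, rng):
        n = 20
        p = np.full((n, 2), 0.5)
        assert soft_delta_rmst(p, rng.uniform(1, 80, n), np.ones(n), 60.0) \
            == pytest.approx(0.0, abs=1e-9)

    def test_unit_weights_match_km_curve(self):
        ctx = _SoftKMContext([10, 20, 30, 40], [1, 0, 1, 1], 60.0)
        tau, _ = ctx.value_and_grad(np.ones(4))
        assert tau == pytest.approx(28.75, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        n = 30
        times = rng.uniform(1, 80, n)
        events = (rng.random(n) < 0.6).astype(float)
        ctx = _SoftKMContext(times, events, 60.0)
        w = rng.uniform(0.05, 1.0, n)
        _, grad = ctx.value_and_grad(w)
        eps = 1e-6
        for j in range(n):
            wp, wm = w.copy(), w.copy()
            wp[j] += eps
            wm[j] -= eps
            fd = (ctx.value_and_grad(wp)[0] - ctx.value_and_grad(wm)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_separable_pair_high_accuracy(self, small_labelled_pair):
        src, tgt = small_labelled_pair
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=400, seed=0)
        model, _ = train(src, tgt, cfg)
        acc = (predict_subtype(model, tgt.x) == tgt.labels).mean()
        assert acc >= 0.9

    def test_pure_supervised_never_reads_target_survival(self, small_labelled_pair):
        src, tgt = small_labelled_pair
        # strip survival: training with omega2=0 must not need it
        tgt_bare = tgt.subset(np.arange(tgt.n_samples))
        tgt_bare.clinical = {}
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=200, omega2=0.0, seed=0)
        model, logs = train(src, tgt_bare, cfg)
        assert np.all(np.isnan(logs.reward))
        acc = (predict_subtype(model, src.x) == src.labels).mean()
        assert acc == 1.0

    def test_seeded_runs_bitwise_identical(self, small_labelled_pair):
        src, tgt = small_labelled_pair
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=150, seed=11)
        m1, l1 = train(src, tgt, cfg)
        m2, l2 = train(src, tgt, cfg)
        np.testing.assert_array_equal(m1.theta, m2.theta)
        np.testing.assert_array_equal(l1.loss, l2.loss)
        np.testing.assert_array_equal(l1.reward, l2.reward)

    def test_early_stop_returns_best_validation_snapshot(self, small_labelled_pair):
        src, tgt = small_labelled_pair
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=200, seed=0,
                         early_stop=True, eval_every=20)
        model, logs = train(src, tgt, cfg, validation=tgt)
        assert logs.best_episode >= 0
        assert logs.val_delta_rmst.max() == logs.val_delta_rmst[
            list(logs.val_episodes).index(logs.best_episode)]

    def test_baseline_tracks_reward(self, small_labelled_pair):
        """Gradient descent on the baseline loss drives the mean residual
        toward zero (least-squares convergence)."""
        src, tgt = small_labelled_pair
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=600, seed=0)
        _, logs = train(src, tgt, cfg)
        early = logs.l_bl[50:100].mean()
        late = logs.l_bl[-50:].mean()
        assert late < early

    def test_soft_ablation_trains(self, small_labelled_pair):
        src, tgt = small_labelled_pair
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=300, seed=0)
        model, logs = train_soft_ablation(src, tgt, cfg)
        acc = (predict_subtype(model, tgt.x) == tgt.labels).mean()
        assert acc >= 0.9
        # the soft RMST gap (logged as reward) improves over training
        assert logs.reward[-20:].mean() > logs.reward[:20].mean()


class TestSerialization:
    def test_round_trip(self, tmp_path, small_labelled_pair, rng):
        src, tgt = small_labelled_pair
        cfg = SrpsConfig(k=2, d=src.x.shape[1], episodes=50, seed=0)
        model, _ = train(src, tgt, cfg)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.theta, model.theta)
        x = rng.normal(size=(5, src.x.shape[1]))
        np.testing.assert_array_equal(predict_subtype(back, x), predict_subtype(model, x))
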