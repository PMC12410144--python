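"""Encoder, sampling, decoders, KL and topic loss of the neural topic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survtopic.autodiff as ad
from survtopic.autodiff import Tensor
from survtopic.scholar import (
    PosteriorStats,
    PriorConstants,
    ScholarModel,
    estimate_topic_weights,
    kl_to_prior,
    sample_topic_weights,
    topic_loss,
    word_distribution,
)


class TestPriorConstants:
    def test_sigma0_formula(self):
        prior = PriorConstants(k=5, alpha=2.0)
        np.testing.assert_allclose(prior.sigma0_sq, np.full(5, 4 / 10))
        np.testing.assert_allclose(prior.mu0, 0.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PriorConstants(k=0, alpha=1.0)
        with pytest.raises(ValueError):
            PriorConstants(k=3, alpha=0.0)


class TestEncode:
    def test_zero_weights_return_bias(self):
        model = ScholarModel(n_events=5, k=3, seed=0)
        for name in ("enc.W1", "enc.Wmu", "enc.Wsig"):
            model.params[name].value[:] = 0.0
        model.params["enc.bmu"].value[:] = [1.0, 2.0, 3.0]
        post = model.encode(np.full(5, 0.2))
        np.testing.assert_allclose(post.mu, [1.0, 2.0, 3.0])

    def test_eval_mode_is_deterministic(self):
        model = ScholarModel(n_events=8, k=4, seed=1)
        x = np.random.default_rng(0).dirichlet(np.ones(8))
        a, b = model.encode(x), model.encode(x)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.log_sigma_sq, b.log_sigma_sq)

    def test_output_shapes(self):
        model = ScholarModel(n_events=6, k=3, seed=2)
        post = model.encode(np.full((5, 6), 1 / 6))
        assert post.mu.shape == (5, 3) and post.log_sigma_sq.shape == (5, 3)

    def test_dimension_mismatch_raises(self):
        model = ScholarModel(n_events=6, k=3, seed=2)
        with pytest.raises(ValueError):
            model.encode(np.full(4, 0.25))


class TestSampling:
    def test_zero_variance_gives_softmax_of_mu(self):
        mu = np.array([1.0, -2.0, 0.5])
        post = PosteriorStats(mu, np.full(3, -700.0))  # sigma ~ 0
        out = sample_topic_weights(post, np.random.default_rng(0).standard_normal(3))
        np.testing.assert_allclose(out, ad.softmax(Tensor(mu)).value, atol=1e-12)

    def test_constant_mu_gives_uniform(self):
        post = PosteriorStats(np.full(4, 2.0), np.full(4, -700.0))
        out = sample_topic_weights(post, np.zeros(4))
        np.testing.assert_allclose(out, 0.25, atol=1e-12)

    def test_simplex_output(self):
        rng = np.random.default_rng(5)
        post = PosteriorStats(rng.normal(size=6), rng.normal(size=6))
        out = sample_topic_weights(post, rng.standard_normal(6))
        assert np.all(out > 0)
        assert abs(out.sum() - 1) < 1e-12

    def test_estimate_matches_single_sample_when_deterministic(self):
        post = PosteriorStats(np.array([0.3, -0.7]), np.full(2, -700.0))
        est = estimate_topic_weights(post, n_samples=17, seed=3)
        np.testing.assert_allclose(est, ad.softmax(Tensor(post.mu)).value, atol=1e-12)

    def test_estimate_agrees_with_independent_monte_carlo(self):
        # oracle: direct (non-reparameterized) Monte-Carlo mean at 10^6 draws
        rng = np.random.default_rng(11)
        mu, log_s2 = rng.normal(size=3), rng.normal(size=3) - 1
        post = PosteriorStats(mu, log_s2)
        est = estimate_topic_weights(post, n_samples=10_000, seed=4)
        draws = rng.normal(mu, np.exp(0.5 * log_s2), size=(1_000_000, 3))
        e = np.exp(draws - draws.max(axis=1, keepdims=True))
        oracle_samples = e / e.sum(axis=1, keepdims=True)
        oracle = oracle_samples.mean(axis=0)
        se = oracle_samples.std(axis=0) / 1000 + oracle_samples.std(axis=0) / 100
        assert np.all(np.abs(est - oracle) < 3 * se)

    def test_invalid_n_samples(self):
        post = PosteriorStats(np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            estimate_topic_weights(post, n_samples=0)


class TestWordDistribution:
    def test_lda_one_hot_selects_topic_row(self):
        model = ScholarModel(n_events=7, k=3, decoder="lda", seed=3)
        W = np.array([0.0, 1.0, 0.0])
        expected = ad.softmax(Tensor(model.params["dec.H"].value[1])).value
        np.testing.assert_allclose(word_distribution(W, model), expected, atol=1e-12)

    def test_sage_zero_deviations_give_background(self):
        model = ScholarModel(n_events=5, k=3, decoder="sage", seed=4)
        model.params["dec.H"].value[:] = 0.0
        model.params["dec.gamma"].value[:] = np.arange(5.0)
        bg = ad.softmax(Tensor(np.arange(5.0))).value
        for W in (np.eye(3)[0], np.full(3, 1 / 3)):
            np.testing.assert_allclose(word_distribution(W, model), bg, atol=1e-12)

    def test_single_topic_ignores_weights(self):
        model = ScholarModel(n_events=4, k=1, decoder="lda", survival="none", seed=5)
        out = word_distribution(np.array([1.0]), model)
        np.testing.assert_allclose(out, ad.softmax(Tensor(model.params["dec.H"].value[0])).value)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_simplex_invariant(self, seed):
        rng = np.random.default_rng(seed)
        model = ScholarModel(n_events=6, k=3, decoder=rng.choice(["lda", "sage"]), seed=seed % 100)
        W = rng.dirichlet(np.ones(3), size=4)
        zeta = word_distribution(W, model)
        assert np.all(zeta > 0)
        np.testing.assert_allclose(zeta.sum(axis=1), 1.0, atol=1e-12)


class TestKL:
    def test_zero_at_prior(self):
        prior = PriorConstants(k=3, alpha=0.5)
        post = PosteriorStats(np.zeros(3), np.log(prior.sigma0_sq))
        assert kl_to_prior(post, prior) == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_value(self):
        # k=2, alpha=1 -> sigma0^2 = 0.5; mu=(1,0), sigma^2=(0.5,0.5)
        # per-coordinate: 0.5*[(0.5+mu^2)/0.5 - 1 + log(0.5/0.5)] -> 0.5*[2-1] + 0.5*[1-1] = 1
        prior = PriorConstants(k=2, alpha=1.0)
        post = PosteriorStats(np.array([1.0, 0.0]), np.log([0.5, 0.5]))
        assert kl_to_prior(post, prior) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        prior = PriorConstants(k=4, alpha=float(rng.uniform(0.1, 5)))
        post = PosteriorStats(rng.normal(size=4), rng.normal(size=4))
        assert kl_to_prior(post, prior) >= -1e-12

    def test_monte_carlo_cross_check(self):
        # E_q[log q - log p] estimated by direct sampling
        rng = np.random.default_rng(21)
        prior = PriorConstants(k=3, alpha=1.0)
        mu, log_s2 = rng.normal(size=3), rng.normal(size=3)
        post = PosteriorStats(mu, log_s2)
        closed = kl_to_prior(post, prior)
        s = np.exp(0.5 * log_s2)
        draws = rng.normal(mu, s, size=(1_000_000, 3))
        log_q = -0.5 * (((draws - mu) / s) ** 2 + np.log(2 * np.pi) + log_s2).sum(axis=1)
        s0 = prior.sigma0_sq
        log_p = -0.5 * ((draws**2) / s0 + np.log(2 * np.pi) + np.log(s0)).sum(axis=1)
        diffs = log_q - log_p
        se = diffs.std() / 1000
        assert abs(closed - diffs.mean()) < 3 * se

    def test_nonpositive_variance_rejected(self):
        prior = PriorConstants(k=2, alpha=1.0)
        with pytest.raises(ValueError):
            PosteriorStats(np.zeros(2), np.array([np.inf, 0.0]))


class TestTopicLoss:
    def test_uniform_reconstruction_at_prior(self):
        prior = PriorConstants(k=2, alpha=1.0)
        posts = PosteriorStats(np.zeros((1, 2)), np.tile(np.log(prior.sigma0_sq), (1, 1)))
        xbar = np.full((1, 4), 0.25)
        loss = topic_loss(xbar, np.full((1, 4), 0.25), posts, prior)
        assert loss == pytest.approx(np.log(4), abs=1e-12)

    def test_sage_penalty_reduces_to_lda_form_at_zero(self):
        rng = np.random.default_rng(8)
        prior = PriorConstants(k=3, alpha=1.0)
        posts = PosteriorStats(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        xbar = rng.dirichlet(np.ones(6), size=4)
        zeta = rng.dirichlet(np.ones(6), size=4)
        H = rng.normal(size=(3, 6))
        plain = topic_loss(xbar, zeta, posts, prior)
        with_pen = topic_loss(xbar, zeta, posts, prior, H=H, lambda_small_deviation=0.0)
        assert plain == pytest.approx(with_pen, abs=1e-14)
        penalized = topic_loss(xbar, zeta, posts, prior, H=H, lambda_small_deviation=0.5)
        assert penalized == pytest.approx(plain + 0.5 * (H**2).sum(), rel=1e-12)

    def test_invariant_to_subject_permutation(self):
        rng = np.random.default_rng(9)
        prior = PriorConstants(k=2, alpha=1.0)
        xbar = rng.dirichlet(np.ones(5), size=6)
        zeta = rng.dirichlet(np.ones(5), size=6)
        mu, ls = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        perm = rng.permutation(6)
        a = topic_loss(xbar, zeta, PosteriorStats(mu, ls), prior)
        b = topic_loss(xbar[perm], zeta[perm], PosteriorStats(mu[perm], ls[perm]), prior)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_batch_rejected(self):
        prior = PriorConstants(k=2, alpha=1.0)
        posts = PosteriorStats(np.zeros((0, 2)), np.zeros((0, 2)))
        with pytest.raises(ValueError):
            topic_loss(np.zeros((0, 3)), np.zeros((0, 3)), posts, prior)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        model = ScholarModel(n_events=6, k=3, decoder="sage", survival="aft", seed=6)
        model.save(tmp_path / "ckpt")
        back = ScholarModel.load(tmp_path / "ckpt")
        for name, p in model.params.items():
            np.testing.assert_array_equal(back.params[name].value, p.value)
        x = np.random.default_rng(0).dirichlet(np.ones(6), size=3)
        np.testing.assert_array_equal(back.encode(x).mu, model.encode(x).mu)
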