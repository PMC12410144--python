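"""Cox and AFT losses, Breslow baseline, ranking loss, survival curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survtopic.autodiff import Tensor
from survtopic.survival import (
    AFTHead,
    BaselineSurvival,
    CoxHead,
    _aft_nll_t,
    _cox_loss_t,
    _ranking_loss_t,
    aft_nll,
    breslow_baseline,
    cox_partial_likelihood_loss,
    cox_survival_curve,
    linear_score,
    loglogistic_survival,
    ranking_loss,
)

labels = st.integers(2, 25).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(0.1, 50), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(lambda d: sum(d) > 0),
        st.lists(st.floats(-3, 3), min_size=n, max_size=n),
    )
)


class TestLinearScore:
    def test_background_topic_scores_zero(self):
        head = CoxHead.from_free(np.array([2.0, -1.0]))
        assert linear_score(np.array([0.0, 0.0, 1.0]), head) == 0.0

    def test_zero_coefficients(self):
        head = CoxHead(np.zeros(4))
        W = np.random.default_rng(0).dirichlet(np.ones(4), size=5)
        np.testing.assert_array_equal(linear_score(W, head), np.zeros(5))

    def test_arithmetic(self):
        head = CoxHead(np.array([1.0, -1.0, 0.0]))
        assert linear_score(np.array([0.5, 0.25, 0.25]), head) == pytest.approx(0.25)

    def test_aft_adds_intercept(self):
        head = AFTHead(np.array([1.0, 0.0]), mu=2.0, log_sigma=0.0)
        assert linear_score(np.array([0.5, 0.5]), head) == pytest.approx(2.5)

    def test_background_constraint_enforced(self):
        with pytest.raises(ValueError):
            CoxHead(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            AFTHead(np.array([1.0, 2.0]), mu=0.0, log_sigma=0.0)


def cox_loss_oracle(scores, Y, delta):
    """Direct O(n^2) evaluation of the partial-likelihood loss."""
    scores, Y, delta = map(np.asarray, (scores, Y, delta))
    n = len(scores)
    total = 0.0
    for i in range(n):
        if delta[i] == 1:
            risk = np.exp(scores[Y >= Y[i]]).sum()
            total += scores[i] - np.log(risk)
    return -total / n


class TestCoxLoss:
    def test_single_subject_is_zero(self):
        assert cox_partial_likelihood_loss([0.7], [1.0], [1]) == pytest.approx(0.0, abs=1e-14)

    def test_two_subject_hand_value(self):
        loss = cox_partial_likelihood_loss([0.0, 0.0], [1.0, 2.0], [1, 1])
        assert loss == pytest.approx(np.log(2) / 2, abs=1e-12)

    @given(labels)
    @settings(max_examples=60, deadline=None)
    def test_matches_quadratic_oracle(self, data):
        Y, delta, scores = map(np.array, data)
        ours = cox_partial_likelihood_loss(scores, Y, delta)
        assert ours == pytest.approx(cox_loss_oracle(scores, Y, delta), abs=1e-10)

    @given(labels, st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance(self, data, c):
        Y, delta, scores = map(np.array, data)
        a = cox_partial_likelihood_loss(scores, Y, delta)
        b = cox_partial_likelihood_loss(scores + c, Y, delta)
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_events_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert cox_partial_likelihood_loss([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        n = 12
        scores = rng.normal(size=n)
        Y = rng.uniform(0.1, 5, n)
        delta = rng.integers(0, 2, n)
        delta[0] = 1
        t = Tensor(scores, requires_grad=True)
        _cox_loss_t(t, Y, delta).backward()
        h = 1e-6
        for i in range(n):
            e = np.zeros(n)
            e[i] = h
            fd = (
                cox_partial_likelihood_loss(scores + e, Y, delta)
                - cox_partial_likelihood_loss(scores - e, Y, delta)
            ) / (2 * h)
            assert abs(fd - t.grad[i]) / max(abs(fd), 1e-8) < 1e-4


class TestBreslow:
    def test_hand_computed_baseline(self):
        base = breslow_baseline([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(base.hazards, [1 / 3, 1 / 2, 1.0])
        assert base.survival(3.0) == pytest.approx(np.exp(-11 / 6), abs=1e-12)
        assert base.survival(0.5) == 1.0

    def test_all_censored_gives_unit_survival(self):
        with pytest.warns(RuntimeWarning):
            base = breslow_baseline([0.0, 1.0], [1.0, 2.0], [0, 0])
        np.testing.assert_array_equal(base.survival([0.0, 5.0, 100.0]), 1.0)

    @given(labels)
    @settings(max_examples=40, deadline=None)
    def test_survival_is_nonincreasing(self, data):
        Y, delta, scores = map(np.array, data)
        base = breslow_baseline(scores, Y, delta)
        grid = np.linspace(0, Y.max() * 1.5, 50)
        s = base.survival(grid)
        assert np.all(np.diff(s) <= 1e-12)

    def test_equal_scores_match_nelson_aalen(self):
        # independent oracle: lifelines' Nelson-Aalen estimator
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        n = 80
        Y = np.round(rng.exponential(2, n), 1) + 0.1  # force ties
        delta = rng.integers(0, 2, n)
        delta[:5] = 1
        base = breslow_baseline(np.zeros(n), Y, delta)
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(Y, delta)
        grid = np.unique(Y)
        ours = base.cumulative_hazard(grid)
        theirs = naf.cumulative_hazard_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestCoxCurve:
    def test_zero_score_equals_baseline(self):
        base = BaselineSurvival(np.array([1.0, 2.0]), np.array([0.2, 0.3]))
        curve = cox_survival_curve(0.0, base)
        grid = np.array([0.5, 1.5, 2.5])
        np.testing.assert_allclose(curve(grid), base.survival(grid))

    def test_power_relation(self):
        base = BaselineSurvival(np.array([1.0]), np.array([np.log(2)]))  # S0(t>=1)=0.5
        curve = cox_survival_curve(np.log(2), base)
        assert curve(2.0) == pytest.approx(0.25, abs=1e-12)

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(max_examples=30, deadline=None)
    def test_larger_score_lower_survival(self, a, b):
        lo, hi = min(a, b), max(a, b)
        base = BaselineSurvival(np.array([1.0, 3.0]), np.array([0.5, 0.4]))
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert np.all(cox_survival_curve(lo, base)(grid) >= cox_survival_curve(hi, base)(grid))


class TestAFT:
    def test_event_at_median_value(self):
        # z = 0, sigma = 1: -log f_eps(0) = log 4
        assert aft_nll([0.0], 0.0, [1.0], [1]) == pytest.approx(np.log(4), abs=1e-12)

    def test_censored_at_median_value(self):
        assert aft_nll([0.0], 0.0, [1.0], [0]) == pytest.approx(np.log(2), abs=1e-12)

    def test_far_censored_contribution_vanishes(self):
        # z -> -infinity: censored subject contributes ~0
        assert aft_nll([50.0], 0.0, [1.0], [0]) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            aft_nll([0.0], 0.0, [0.0], [1])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        n = 10
        loc = rng.normal(size=n)
        Y = rng.uniform(0.2, 6, n)
        delta = rng.integers(0, 2, n)
        t = Tensor(loc, requires_grad=True)
        ls = Tensor(0.3, requires_grad=True)
        (_aft_nll_t(t, ls, Y, delta) + _ranking_loss_t(t, Y, delta)).backward()
        h = 1e-6
        for i in range(n):
            e = np.zeros(n)
            e[i] = h
            fd = (
                aft_nll(loc + e, 0.3, Y, delta) + ranking_loss(loc + e, Y, delta)
                - aft_nll(loc - e, 0.3, Y, delta) - ranking_loss(loc - e, Y, delta)
            ) / (2 * h)
            assert abs(fd - t.grad[i]) / max(abs(fd), 1e-8) < 1e-4
        fd_s = (aft_nll(loc, 0.3 + h, Y, delta) - aft_nll(loc, 0.3 - h, Y, delta)) / (2 * h)
        assert abs(fd_s - float(ls.grad)) < 1e-5

    def test_density_consistent_with_survival_curve(self):
        # f(t) implied by the NLL must match -dS/dt by central differences
        loc, sigma = 0.8, 0.6
        ts = np.linspace(0.5, 4.0, 8)
        h = 1e-5
        for t0 in ts:
            nll = aft_nll([loc], np.log(sigma), [t0], [1])
            # aft_nll returns -log f_eps(z) + log sigma = -log[t * f_T(t)]
            f_t = np.exp(-nll) / t0
            dS = (
                loglogistic_survival(loc, sigma, t0 - h) - loglogistic_survival(loc, sigma, t0 + h)
            ) / (2 * h)
            assert abs(f_t - dS) < 1e-6


class TestRankingLoss:
    def test_equal_locations_give_zero(self):
        assert ranking_loss([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_arithmetic(self):
        # location difference log 3: log2(1 + 3) - 1 = 1
        assert ranking_loss([np.log(3), 0.0], [1.0, 2.0], [1, 0]) == pytest.approx(1.0, rel=1e-12)

    def test_empty_pair_set_returns_zero(self):
        assert ranking_loss([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0

    def test_decreases_as_concordant_gap_widens(self):
        Y, delta = np.array([1.0, 5.0]), np.array([1, 0])
        # longer-lived subject j gets increasingly larger location
        losses = [ranking_loss([0.0, g], Y, delta) for g in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(losses) < 0)


class TestLogLogistic:
    def test_boundary_and_median(self):
        assert loglogistic_survival(1.3, 0.7, 0.0) == 1.0
        assert loglogistic_survival(1.3, 0.7, np.exp(1.3)) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(-2, 2), st.floats(0.1, 3))
    @settings(max_examples=40, deadline=None)
    def test_strictly_decreasing(self, loc, sigma):
        grid = np.linspace(0.01, 20, 50)
        s = loglogistic_survival(loc, sigma, grid)
        assert np.all(np.diff(s) < 0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            loglogistic_survival(0.0, 0.0, 1.0)


class TestCurveExport:
    def test_csv_roundtrip(self, tmp_path):
        from survtopic.survival import export_curve_csv, loglogistic_survival_curve
        import pandas as pd

        curve = loglogistic_survival_curve(0.5, 0.8)
        grid = np.linspace(0, 5, 11)
        out = tmp_path / "curve.csv"
        export_curve_csv(curve, grid, out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["time", "survival"]
        np.testing.assert_allclose(df["survival"], curve(grid), atol=1e-6)
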