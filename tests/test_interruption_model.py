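"""interruption_model: design, pulse, densities, gradient, oracle equality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screengap import data_io as dio
from screengap import interruption_model as im
from screengap import synthetic_data as sd


@pytest.fixture(scope="module")
def toy_model(calendar):
    """3 groups x 10 weeks straddling the interruption envelope."""
    cfg = sd.CountSimConfig(
        groups={"a": 50.0, "b": 80.0, "c": 20.0},
        date_range=("2020-02-16", "2020-04-19"),
        window_start="2020-03-15", window_end="2020-04-05",
        seed=3,
    )
    series, _ = sd.simulate_weekly_counts(cfg)
    assert series.n_weeks == 10
    return im.CountModel(series, calendar, im.ModelSpec())


class TestBuildDesign:
    def test_zero_harmonics_gives_empty_seasonal_block(self, calendar):
        weeks = dio.week_grid("2020-01-05", "2020-03-01")
        d = im.build_design(weeks, calendar, K=0)
        assert d.seasonal.shape == (len(weeks), 0)

    def test_phase_origin(self, calendar):
        weeks = dio.week_grid("2020-01-05", "2020-03-01")
        d = im.build_design(weeks, calendar, K=3)
        np.testing.assert_allclose(d.seasonal[0, 0::2], 0.0)  # sines at w=0
        np.testing.assert_allclose(d.seasonal[0, 1::2], 1.0)  # cosines at w=0

    def test_annual_periodicity(self, calendar):
        weeks = dio.week_grid("2018-01-07", "2022-12-25")
        d = im.build_design(weeks, calendar, K=2)
        w = 10.0
        for k in (1, 2):
            ang1 = 2 * np.pi * k * w / im.WEEKS_PER_YEAR
            ang2 = 2 * np.pi * k * (w + im.WEEKS_PER_YEAR) / im.WEEKS_PER_YEAR
            assert abs(np.sin(ang1) - np.sin(ang2)) < 1e-9

    def test_negative_k_rejected(self, calendar):
        with pytest.raises(ValueError):
            im.build_design(dio.week_grid("2020-01-05", "2020-02-02"), calendar, K=-1)

    def test_holiday_column_is_binary(self, calendar):
        weeks = dio.week_grid("2019-01-06", "2021-12-26")
        d = im.build_design(weeks, calendar, K=2)
        assert set(np.unique(d.holiday)) <= {0.0, 1.0}


class TestInterruptionWeight:
    def test_far_field_is_one(self):
        assert im.interruption_weight(-20.0, 0.0, 10.0, 0.5) > 0.999

    def test_deep_window_is_zero(self):
        assert im.interruption_weight(5.0, 0.0, 10.0, 0.5) < 0.001

    def test_small_ramp_converges_to_step(self):
        t = np.linspace(-5, 15, 401)
        step = ((t > 0.0) & (t < 10.0)).astype(float)
        for s in (0.1, 0.03, 0.01):
            tau = im.interruption_weight(t, 0.0, 10.0, s)
            inside = np.abs(t - 0.0) > 0.5
            inside &= np.abs(t - 10.0) > 0.5
            assert np.max(np.abs((1.0 - tau)[inside] - step[inside])) < 4.0 * s

    def test_nonpositive_ramp_rejected(self):
        with pytest.raises(ValueError):
            im.interruption_weight(1.0, 0.0, 2.0, 0.0)


class TestMeanProcess:
    def test_boundaries_and_midpoint(self):
        assert im.mean_process(1.0, 7.0, 2.0) == 7.0
        assert im.mean_process(0.0, 7.0, 2.0) == 2.0
        assert im.mean_process(0.5, 7.0, 2.0) == 4.5

    def test_affine_bounds_hold_for_any_tau(self):
        rng = np.random.default_rng(1)
        tau = rng.random(100)
        xb, xw = rng.normal(size=100), rng.normal(size=100)
        mu = im.mean_process(tau, xb, xw)
        assert np.all(mu <= np.maximum(xb, xw) + 1e-12)
        assert np.all(mu >= np.minimum(xb, xw) - 1e-12)

    def test_tau_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            im.mean_process(1.5, 1.0, 0.0)


class TestObservationDensity:
    def test_zero_count_closed_form(self):
        # Poisson(0 | lam=3) log-density is -3; eps term is the standard normal mode
        val = im.observation_logdensity(
            y=np.array([0.0]), mu=np.array([np.log(3.0)]), H=np.array([0.0]),
            S=np.zeros((1, 0)), beta_H=0.0, beta_S=np.zeros(0),
            eps=np.array([0.0]), sigma_eps=1.0,
        )
        expected = -3.0 + stats.norm.logpdf(0.0)
        assert abs(val - expected) < 1e-12

    def test_three_week_series_matches_term_sum(self):
        rng = np.random.default_rng(2)
        y = np.array([4.0, 0.0, 7.0])
        mu = rng.normal(1.0, 0.3, 3)
        H = np.array([0.0, 1.0, 0.0])
        S = rng.normal(size=(3, 2))
        bS = np.array([0.1, -0.2])
        eps = rng.normal(0, 0.1, 3)
        total = im.observation_logdensity(y, mu, H, S, 0.3, bS, eps, 0.1)
        oracle = sum(
            stats.poisson.logpmf(y[t], np.exp(mu[t] + H[t] * 0.3 + S[t] @ bS + eps[t]))
            + stats.norm.logpdf(eps[t], 0, 0.1)
            for t in range(3)
        )
        assert abs(total - oracle) < 1e-10

    def test_covariate_free_reduction(self):
        val = im.observation_logdensity(
            y=np.array([5.0]), mu=np.array([1.2]), H=np.array([0.0]),
            S=np.zeros((1, 1)), beta_H=9.9, beta_S=np.array([0.0]),
            eps=np.array([0.0]), sigma_eps=0.5,
        )
        expected = stats.poisson.logpmf(5, np.exp(1.2)) + stats.norm.logpdf(0, 0, 0.5)
        assert abs(val - expected) < 1e-12

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            im.observation_logdensity(np.array([1.0]), np.array([0.0]), np.array([0.0]),
                                      np.zeros((1, 0)), 0.0, np.zeros(0),
                                      np.array([0.0]), 0.0)


class TestStateTransition:
    def test_zero_increment_is_mode(self):
        base = im.state_transition_logdensity(1.0, 1.0, 0.2)
        assert base > im.state_transition_logdensity(1.0, 1.1, 0.2)

    def test_halving_scale_quadruples_penalty(self):
        inc_pen = lambda s: (im.state_transition_logdensity(0.0, 0.0, s)
                             - im.state_transition_logdensity(0.0, 0.4, s))
        assert abs(inc_pen(0.1) / inc_pen(0.2) - 4.0) < 1e-12

    def test_shift_invariance(self):
        a = im.state_transition_logdensity(1.0, 1.3, 0.2)
        b = im.state_transition_logdensity(5.0, 5.3, 0.2)
        assert abs(a - b) < 1e-12


class TestJointDensity:
    def test_matches_brute_force_term_sum(self, toy_model):
        rng = np.random.default_rng(0)
        for _ in range(3):
            theta = toy_model.initial_theta(rng) + 0.1 * rng.standard_normal(toy_model.dim)
            lp = toy_model.logp(theta)
            bf = im.brute_force_joint_logp(toy_model, theta)
            assert abs(lp - bf) < 1e-8

    def test_gradient_matches_finite_differences(self, toy_model):
        rng = np.random.default_rng(4)
        theta = toy_model.initial_theta(rng)
        _, grad = toy_model.logp_and_grad(theta)
        eps = 1e-6
        for i in rng.choice(toy_model.dim, 40, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (toy_model.logp(tp) - toy_model.logp(tm)) / (2 * eps)
            assert abs(num - grad[i]) <= 1e-4 * max(1.0, abs(num))

    def test_negbin_gradient_matches_finite_differences(self, calendar):
        cfg = sd.CountSimConfig(groups={"a": 30.0}, seed=9,
                                date_range=("2020-02-16", "2020-04-19"),
                                window_start="2020-03-15", window_end="2020-04-05")
        series, _ = sd.simulate_weekly_counts(cfg)
        model = im.CountModel(series, calendar, im.ModelSpec(family="negbin"))
        rng = np.random.default_rng(5)
        theta = model.initial_theta(rng)
        _, grad = model.logp_and_grad(theta)
        eps = 1e-6
        for i in rng.choice(model.dim, 30, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (model.logp(tp) - model.logp(tm)) / (2 * eps)
            assert abs(num - grad[i]) <= 1e-4 * max(1.0, abs(num))

    def test_tau_pinned_outside_envelope(self, toy_model):
        rng = np.random.default_rng(6)
        c = toy_model.constrain(toy_model.initial_theta(rng))
        outside = toy_model.envelope_mask == 0.0
        assert outside.any()
        np.testing.assert_allclose(c["tau"][:, outside], 1.0)

    def test_all_zero_group_rejected(self, calendar):
        series = dio.WeeklyCounts(
            ["a", "b"], dio.week_grid("2020-01-05", "2020-03-01"),
            np.vstack([np.ones(9, dtype=int), np.zeros(9, dtype=int)]),
        )
        with pytest.raises(ValueError, match="b"):
            im.CountModel(series, calendar)


class TestModelSpec:
    def test_yaml_dict_round_trip(self):
        spec = im.ModelSpec(K=3, ramp_weeks=0.1)
        back = im.ModelSpec.from_dict(spec.to_dict())
        assert back.K == 3 and back.ramp_weeks == 0.1
        assert back.d0_bounds == spec.d0_bounds

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            im.ModelSpec(family="gaussian")
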