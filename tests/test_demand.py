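"""Exponential demand model: identities, fitting, exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from socialoperant.demand import (
    between_session_consumption,
    fit_cohort,
    fit_demand_curve,
    population_demand_curve,
    predict_consumption,
    shared_k,
    within_session_consumption,
)

PRICES = np.array([1.0, 2.0, 4.0, 6.0, 9.0, 12.0])


class TestPredictConsumption:
    @pytest.mark.parametrize("q0,alpha,k", [(10, 0.01, 2), (3.5, 0.0, 1.2),
                                            (200, 1e-4, 3)])
    def test_null_cost_identity(self, q0, alpha, k):
        assert predict_consumption(q0, alpha, k, 0.0) == q0

    def test_closed_form_value(self):
        # independent high-precision evaluation: 20 * 10**(2*(e**-1 - 1))
        expected = 20 * 10 ** (2 * (np.exp(-1.0) - 1))
        assert predict_consumption(20, 0.005, 2, 10) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.088, abs=5e-4)

    def test_inelastic_limit_flat(self):
        q = predict_consumption(7.0, 0.0, 2.0, PRICES)
        assert np.allclose(q, 7.0)

    def test_monotone_nonincreasing_strict_when_elastic(self):
        c = np.linspace(0, 30, 200)
        q = predict_consumption(12, 0.004, 2, c)
        assert np.all(np.diff(q) < 0)
        assert np.all(q > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            predict_consumption(0.0, 0.01, 2, 1)
        with pytest.raises(ValueError):
            predict_consumption(5, 0.01, 0.0, 1)
        with pytest.raises(ValueError):
            predict_consumption(5, -0.1, 2, 1)


class TestFitDemandCurve:
    def test_noiseless_round_trip(self):
        q = predict_consumption(15, 0.003, 2.0, PRICES)
        fit = fit_demand_curve(PRICES, q, 2.0)
        assert fit.q0 == pytest.approx(15, rel=1e-3)
        assert fit.alpha == pytest.approx(0.003, rel=1e-3)
        assert fit.r_squared >= 0.999
        assert not fit.excluded

    def test_flat_observations_give_zero_elasticity(self):
        fit = fit_demand_curve(PRICES, np.full(6, 8.0), 2.0)
        assert fit.q0 == pytest.approx(8.0, rel=1e-4)
        assert fit.alpha == pytest.approx(0.0, abs=1e-8)
        assert np.isnan(fit.log10_alpha)
        assert not fit.excluded

    def test_noise_inflation_triggers_exclusion(self):
        # log-scale noise inflated until an independent R^2 computation
        # falls below 0.6; the fit must then carry the exclusion flag
        rng = np.random.default_rng(7)
        q_true = predict_consumption(15, 0.003, 2.0, PRICES)
        for sigma in (0.5, 0.8, 1.2, 1.8, 2.5):
            q = q_true * 10 ** rng.normal(0, sigma, PRICES.size)
            fit = fit_demand_curve(PRICES, q, 2.0)
            y = np.log10(q)
            pred = np.log10(fit.predict(PRICES))
            r2_oracle = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
            assert fit.r_squared == pytest.approx(r2_oracle, abs=1e-9)
            if r2_oracle < 0.6:
                assert fit.excluded
                break
        else:
            pytest.fail("noise inflation never produced R^2 < 0.6")

    def test_exclusion_threshold_is_strict_less_than(self):
        q = predict_consumption(15, 0.003, 2.0, PRICES) * 10 ** (
            np.random.default_rng(3).normal(0, 0.3, 6)
        )
        r2 = fit_demand_curve(PRICES, q, 2.0).r_squared
        at = fit_demand_curve(PRICES, q, 2.0, r2_threshold=r2)
        above = fit_demand_curve(PRICES, q, 2.0, r2_threshold=r2 + 1e-9)
        below = fit_demand_curve(PRICES, q, 2.0, r2_threshold=r2 - 1e-9)
        assert not at.excluded  # r2 < r2 is false
        assert above.excluded
        assert not below.excluded

    def test_too_few_positive_points_unfittable(self):
        fit = fit_demand_curve([1, 2, 4], [5.0, 0.0, 0.0], 2.0)
        assert not fit.fittable and fit.excluded
        assert fit.n_points_used == 1

    def test_zero_policy_floor_keeps_points(self):
        fit = fit_demand_curve(
            PRICES, [10, 8, 5, 2, 0, 0], 2.0, zero_policy="floor", zero_floor=0.1
        )
        assert fit.n_points_used == 6

    def test_rejects_nonpositive_prices(self):
        with pytest.raises(ValueError):
            fit_demand_curve([0, 1, 2], [5, 4, 3], 2.0)


def test_shared_k_from_consumption_range():
    assert shared_k([2.0, 20.0, 0.0]) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        shared_k([0.0, 0.0])


class TestBetweenSessionConsumption:
    def test_adjusted_rewards_arithmetic(self):
        out = between_session_consumption(
            pd.DataFrame(
                {
                    "subject_id": ["a"] * 3,
                    "fr": [2, 2, 2],
                    "active_presses": [40, 44, 48],
                }
            )
        )
        assert out.loc[0, "consumption"] == pytest.approx((20 + 22 + 24) / 3)

    def test_adjusted_measure_is_continuous(self):
        out = between_session_consumption(
            pd.DataFrame({"subject_id": ["a"], "fr": [4], "active_presses": [25]})
        )
        assert out.loc[0, "consumption"] == pytest.approx(6.25)

    def test_missing_fr_level_warns(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "a"], "fr": [1, 2], "active_presses": [10, 10]}
        )
        with pytest.warns(UserWarning, match="missing FR"):
            between_session_consumption(df, fr_levels=[1, 2, 4])


class TestWithinSessionConsumption:
    def test_mean_rewards_per_bin(self):
        rows = [
            {"subject_id": "a", "session_id": f"s{i}", "condition": "same",
             "fr": 1, "rewards": r}
            for i, r in enumerate([6, 6, 5, 7])
        ]
        out = within_session_consumption(pd.DataFrame(rows))
        assert out.loc[0, "consumption"] == pytest.approx(6.0)

    def test_zero_rewards_bin_gives_zero(self):
        rows = [
            {"subject_id": "a", "session_id": f"s{i}", "condition": "same",
             "fr": 12, "rewards": 0}
            for i in range(4)
        ]
        out = within_session_consumption(pd.DataFrame(rows))
        assert out.loc[0, "consumption"] == 0.0

    def test_fewer_sessions_warns(self):
        rows = [{"subject_id": "a", "session_id": "s0", "condition": "same",
                 "fr": 1, "rewards": 5}]
        with pytest.warns(UserWarning, match="expected 4"):
            within_session_consumption(pd.DataFrame(rows))


class TestPopulationCurve:
    def _obs(self, subjects):
        rows = []
        for sid, q0 in subjects:
            q = predict_consumption(q0, 0.003, 2.0, PRICES)
            rows += [
                {"subject_id": sid, "sex": "F", "price": c, "consumption": v}
                for c, v in zip(PRICES, q)
            ]
        return pd.DataFrame(rows)

    def test_identical_subjects_match_individual_fit(self):
        obs = self._obs([("a", 10), ("b", 10)])
        pop = population_demand_curve(obs, ["sex"], k_policy="fixed", k_value=2.0)
        ind = fit_demand_curve(
            PRICES, predict_consumption(10, 0.003, 2.0, PRICES), 2.0
        )
        assert pop.loc[0, "q0"] == pytest.approx(ind.q0, rel=1e-6)
        assert pop.loc[0, "alpha"] == pytest.approx(ind.alpha, rel=1e-5)

    def test_mixed_group_q0_between_members(self):
        obs = self._obs([("a", 10), ("b", 20)])
        pop = population_demand_curve(obs, ["sex"], k_policy="fixed", k_value=2.0)
        # oracle: the fit is applied to the price-wise averaged curve
        mean_q = obs.groupby("price")["consumption"].mean()
        oracle = fit_demand_curve(mean_q.index.to_numpy(), mean_q.to_numpy(), 2.0)
        assert pop.loc[0, "q0"] == pytest.approx(oracle.q0, rel=1e-9)
        assert 10 < pop.loc[0, "q0"] < 20

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            population_demand_curve(self._obs([("a", 10)]), ["sex"])


def test_fit_cohort_shared_k_and_exclusion_flags():
    rng = np.random.default_rng(11)
    rows = []
    for sid, sigma in [("good", 0.05), ("bad", 2.0)]:
        q = predict_consumption(15, 0.004, 2.0, PRICES)
        q = q * 10 ** rng.normal(0, sigma, PRICES.size)
        rows += [{"subject_id": sid, "price": c, "consumption": v}
                 for c, v in zip(PRICES, q)]
    fits = fit_cohort(pd.DataFrame(rows))
    assert fits["k"].nunique() == 1  # shared-k convention
    assert set(fits["excluded"]) == {
        bool(r < 0.6) for r in fits["r_squared"]
    } or all(fits["excluded"] == (fits["r_squared"] < 0.6))
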