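"""Simulation engine: conversions, trajectories, invariants."""

import numpy as np
import pandas as pd
import pytest

from bflact.behavior import InitiationModel, IntentModel
from bflact.engine import (SimClock, TransitionRates, monthly_to_per_step,
                           run_cohort, run_one_agent)
from bflact.population import sample_cohort

ALWAYS_INTEND = IntentModel(intercept=40.0)
ALWAYS_INITIATE = InitiationModel(intercept=40.0)
NEVER_INITIATE = InitiationModel(intercept=-40.0)
ZERO_RATES = TransitionRates(0.0, 0.0, 0.0)


def no_barrier_cohort(params, n, seed):
    co = sample_cohort(n, params, seed)
    co["lactation_problem_time"] = np.nan
    co["return_to_work_time"] = np.nan
    return co


class TestMonthlyToPerStep:
    @pytest.mark.parametrize("p_month, per_day", [
        (0.139, 0.0049049), (0.059, 0.0019959), (0.0, 0.0),
    ])
    def test_known_values(self, p_month, per_day):
        assert monthly_to_per_step(p_month) == pytest.approx(per_day,
                                                             abs=1e-6)

    @pytest.mark.parametrize("p_month", [0.016, 0.2, 0.8])
    def test_compounding_recovers_monthly(self, p_month):
        q = monthly_to_per_step(p_month, month_length=30.4375)
        assert 1 - (1 - q) ** 30.4375 == pytest.approx(p_month, rel=1e-12)

    def test_degenerate_one_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert monthly_to_per_step(1.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            monthly_to_per_step(-0.1)


class TestClock:
    def test_eval_days_unique_and_ordered(self):
        clock = SimClock()
        assert clock.eval_days == (30, 91, 183)
        assert clock.horizon_day == 183

    def test_collapsing_eval_months_rejected(self):
        clock = SimClock(eval_months=(1.0, 1.001))
        with pytest.raises(ValueError, match="same day"):
            clock.eval_days


class TestTrajectories:
    def test_no_transition_sources_constant_exclusive(self, params):
        co = no_barrier_cohort(params, 300, seed=1)
        res = run_cohort(co, ALWAYS_INTEND, ALWAYS_INITIATE, ZERO_RATES,
                         exclusive_share=1.0, seed=2, record="daily")
        assert res.initiated.all()
        assert (res.statuses == 2).all()

    def test_never_initiate_formula_throughout(self, params):
        co = sample_cohort(300, params, seed=3)
        res = run_cohort(co, ALWAYS_INTEND, NEVER_INITIATE, ZERO_RATES,
                         exclusive_share=0.5, seed=4, record="daily")
        assert not res.initiated.any()
        assert (res.statuses == 0).all()
        rates = res.outcome_rates()
        for key in ("any_bf_1m", "any_bf_3m", "any_bf_6m"):
            assert rates[key] == 0.0

    def test_status_monotone_and_formula_absorbing(self, params):
        """Feeding level never increases along any trajectory; formula is
        absorbing (full default run, daily resolution)."""
        co = sample_cohort(2000, params, seed=5)
        res = run_cohort(co, seed=6, record="daily")
        diffs = np.diff(res.statuses.astype(int), axis=1)
        assert (diffs <= 0).all()
        hit = np.cumsum(res.statuses == 0, axis=1) > 0
        assert (res.statuses[hit] == 0).all()

    def test_prevalence_orderings(self, params):
        co = sample_cohort(3000, params, seed=7)
        rates = run_cohort(co, seed=8).outcome_rates()
        any_v = [rates[f"any_bf_{m}m"] for m in (1, 3, 6)]
        excl_v = [rates[f"excl_bf_{m}m"] for m in (1, 3, 6)]
        assert any_v[0] >= any_v[1] >= any_v[2]
        assert all(e <= a for e, a in zip(excl_v, any_v))
        assert rates["any_bf_1m"] <= rates["initiation"]

    def test_seed_reproducible_bitwise(self, params):
        co = sample_cohort(500, params, seed=9)
        a = run_cohort(co, seed=10, record="daily")
        b = run_cohort(co, seed=10, record="daily")
        assert np.array_equal(a.statuses, b.statuses)
        assert np.array_equal(a.intent, b.intent)
        assert np.array_equal(a.initiated, b.initiated)

    def test_agent_order_invariance(self, params):
        """Permuting cohort rows with a fixed seed leaves every woman's
        trajectory unchanged (per-agent streams keyed to agent id)."""
        co = sample_cohort(100, params, seed=11)
        perm = co.sample(frac=1.0, random_state=12).reset_index(drop=True)
        a = run_cohort(co, seed=13, record="daily").to_frame()
        b = run_cohort(perm, seed=13, record="daily").to_frame()
        pd.testing.assert_frame_equal(
            a.sort_values("id").reset_index(drop=True),
            b.sort_values("id").reset_index(drop=True))

    def test_missing_fields_rejected(self, params):
        co = sample_cohort(20, params, seed=14)
        co.loc[3, "knowledge"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            run_cohort(co, seed=15)

    def test_run_one_agent_matches_single_row_cohort(self, params):
        co = sample_cohort(1, params, seed=16)
        a = run_one_agent(co.iloc[0], seed=17)
        b = run_cohort(co, seed=17, record="daily")
        assert np.array_equal(a.statuses, b.statuses)


class TestCompetingRiskSurvival:
    def test_exclusive_survival_matches_analytic(self, params):
        """Micro-simulated exclusive-state survival to 1 month matches the
        independent closed form within 0.3pp.

        With no barriers and daily competing hazards q_ep, q_ef, remaining
        exclusive requires surviving both risks on each of the postpartum
        days up to the evaluation instant.
        """
        rates = TransitionRates()  # published final values
        clock = SimClock()
        n_days = clock.eval_days[0] - clock.first_postpartum_day + 1
        q_ep = 1 - (1 - rates.excl_to_partial) ** (1 / clock.month_length)
        q_ef = 1 - (1 - rates.excl_to_formula) ** (1 / clock.month_length)
        analytic = 100 * (1 - q_ep - q_ef) ** n_days

        co = no_barrier_cohort(params, 200_000, seed=18)
        res = run_cohort(co, ALWAYS_INTEND, ALWAYS_INITIATE, rates,
                         exclusive_share=1.0, seed=19)
        sim = res.outcome_rates()["excl_bf_1m"]
        assert sim == pytest.approx(analytic, abs=0.3)

    def test_partial_survival_matches_analytic(self, params):
        rates = TransitionRates()
        clock = SimClock()
        n_days = clock.eval_days[0] - clock.first_postpartum_day + 1
        q_pf = 1 - (1 - rates.partial_to_formula) ** (1 / clock.month_length)
        analytic = 100 * (1 - q_pf) ** n_days

        co = no_barrier_cohort(params, 200_000, seed=20)
        res = run_cohort(co, ALWAYS_INTEND, ALWAYS_INITIATE, rates,
                         exclusive_share=0.0, seed=21)
        assert res.outcome_rates()["any_bf_1m"] == pytest.approx(analytic,
                                                                 abs=0.3)


class TestNetworkInertness:
    def test_zero_peer_weight_network_invariant(self, params):
        """With peer_weight = 0 all outcomes are bitwise invariant to the
        presence of the peer network."""
        from bflact.network import build_network
        co = sample_cohort(800, params, seed=22)
        net = build_network(co, mean_degree=6, seed=23)
        a = run_cohort(co, seed=24, record="daily")
        b = run_cohort(co, seed=24, network=net, record="daily")
        assert np.array_equal(a.statuses, b.statuses)
        assert np.array_equal(a.intent, b.intent)

    def test_positive_peer_weight_uses_network(self, params):
        from bflact.network import build_network
        co = sample_cohort(800, params, seed=25)
        net = build_network(co, mean_degree=6, seed=26)
        m = IntentModel(intercept=1.0, peer_weight=2.0)
        a = run_cohort(co, m, seed=27)
        b = run_cohort(co, m, network=net, seed=27)
        assert a.intent.mean() != b.intent.mean()
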