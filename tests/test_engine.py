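"""Discounting, half-cycle correction, and the two Markov engines."""

import dataclasses

import numpy as np
import pytest

import ratarget as rt
from conftest import random_state_values, random_transition_model


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,k,cy,expected",
        [
            (0.04, 0, 0.25, 1.0),
            (0.04, 4, 0.25, 1 / 1.04),
            (0.0, 13, 0.25, 1.0),
            (0.015, 8, 0.25, 1.015 ** -2),
        ],
    )
    def test_values(self, rate, k, cy, expected):
        assert rt.discount_factor(rate, k, cy) == pytest.approx(
            expected, abs=1e-12)

    def test_annual_step_compounding(self):
        assert rt.discount_factor(0.04, 3, 0.25, "annual_step") == 1.0
        assert rt.discount_factor(0.04, 4, 0.25, "annual_step") == \
            pytest.approx(1 / 1.04)


def test_half_cycle_value():
    assert rt.half_cycle_value(0.8, 0.6) == pytest.approx(0.7)
    assert rt.half_cycle_value(0.42, 0.42) == pytest.approx(0.42)


def _identity_tm(strategy):
    return rt.TransitionModel.from_probs(
        {k: np.eye(4) for k in strategy.transition_keys})


def _unit_vals(u=1.0, c=0.0):
    return rt.StateValues(
        utilities={s: u for s in rt.HealthState},
        sick_days_per_cycle={s: 0.0 for s in rt.HealthState},
        hc_cost_per_cycle={s: c for s in rt.HealthState},
    )


class TestSimulatePatient:
    def test_stay_in_remission_matches_geometric_closed_form(self, step_up,
                                                             truth_su,
                                                             tariff):
        """Identity matrices from remission: the patient tapers to
        medication-free and total QALY is the discounted geometric sum."""
        vals = truth_su.state_values(tariff)
        u_rem = vals.utilities[rt.HealthState.REMISSION]
        cfg = rt.ModelConfig(initial_state_distribution=(1, 0, 0, 0), seed=3)
        traj = rt.simulate_patient(step_up, _identity_tm(step_up), vals, cfg)
        expected = sum(
            u_rem * 0.25 * 1.015 ** (-0.25 * k) for k in range(20))
        assert traj.total_qaly == pytest.approx(expected, abs=1e-10)
        assert traj.frame.iloc[-1]["mode"] == "medication_free"

    def test_zero_values_give_zero_totals(self, step_up):
        free = rt.build_strategy({
            "name": "free",
            "escalation_ladder": [
                {"name": s.name, "drug_cost_per_cycle": 0.0,
                 "transition_key": s.transition_key}
                for s in step_up.escalation_ladder],
            "taper_ladder": [
                {"name": s.name, "drug_cost_per_cycle": 0.0,
                 "transition_key": s.transition_key}
                for s in step_up.taper_ladder],
        })
        traj = rt.simulate_patient(free, _identity_tm(free),
                                   _unit_vals(0.0, 0.0),
                                   rt.ModelConfig(seed=1))
        assert traj.total_cost == 0.0
        assert traj.total_qaly == 0.0

    def test_same_seed_identical_trajectory(self, step_up, truth_su, tariff):
        vals = truth_su.state_values(tariff)
        tm = truth_su.transition_model()
        cfg = rt.ModelConfig(seed=17)
        t1 = rt.simulate_patient(step_up, tm, vals, cfg)
        t2 = rt.simulate_patient(step_up, tm, vals, cfg)
        assert t1.frame.equals(t2.frame)
        assert t1.total_cost == t2.total_cost

    def test_states_chain_across_cycles(self, step_up, truth_su, tariff):
        traj = rt.simulate_patient(step_up, truth_su.transition_model(),
                                   truth_su.state_values(tariff),
                                   rt.ModelConfig(seed=5))
        ends = traj.frame["state_end"].to_numpy()[:-1]
        starts = traj.frame["state_start"].to_numpy()[1:]
        assert (ends == starts).all()

    def test_totals_equal_cycle_sums(self, step_up, truth_su, tariff):
        traj = rt.simulate_patient(step_up, truth_su.transition_model(),
                                   truth_su.state_values(tariff),
                                   rt.ModelConfig(seed=23))
        assert traj.total_cost == pytest.approx(
            traj.frame["cycle_cost"].sum())
        assert traj.total_qaly == pytest.approx(
            traj.frame["cycle_qaly"].sum())


class TestSimulateCohort:
    def test_n1_matches_single_trajectory(self, step_up, truth_su, tariff):
        vals = truth_su.state_values(tariff)
        tm = truth_su.transition_model()
        cfg = rt.ModelConfig(seed=29, n_patients=1)
        res = rt.simulate_cohort(step_up, tm, vals, cfg)
        traj = rt.simulate_patient(step_up, tm, vals, cfg)
        assert res.mean_cost == pytest.approx(traj.total_cost)
        assert res.mean_qaly == pytest.approx(traj.total_qaly)

    def test_occupancy_rows_sum_to_one(self, combo, truth_combo, tariff):
        res = rt.simulate_cohort(
            combo, truth_combo.transition_model(),
            truth_combo.state_values(tariff),
            rt.ModelConfig(seed=31, n_patients=400))
        assert np.allclose(res.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_n_patients(self):
        with pytest.raises(ValueError):
            rt.ModelConfig(n_patients=0)

    def test_missing_transition_row_named(self, step_up, truth_su, tariff):
        tm = rt.TransitionModel.from_probs(
            {k: np.eye(4) for k in step_up.transition_keys
             if k != "mtx_csdmard"})
        with pytest.raises(KeyError, match="mtx_csdmard"):
            rt.simulate_cohort(step_up, tm, truth_su.state_values(tariff),
                               rt.ModelConfig(seed=1, n_patients=10))

    def test_matches_expectation_oracle(self, step_up, truth_su, tariff):
        """Microsimulation means at n=5,000 agree with the deterministic
        occupancy-propagation oracle within 3 Monte-Carlo SEs."""
        vals = truth_su.state_values(tariff)
        tm = truth_su.transition_model()
        cfg = rt.ModelConfig(seed=37, n_patients=5000)
        micro = rt.simulate_cohort(step_up, tm, vals, cfg)
        exact = rt.cohort_expectation(step_up, tm, vals, cfg)
        for col, mean, ref in [
            ("total_cost", micro.mean_cost, exact.mean_cost),
            ("total_qaly", micro.mean_qaly, exact.mean_qaly),
        ]:
            se = micro.per_patient[col].std(ddof=1) / np.sqrt(cfg.n_patients)
            assert abs(mean - ref) <= 3 * se

    def test_error_shrinks_with_n(self, combo, truth_combo, tariff):
        vals = truth_combo.state_values(tariff)
        tm = truth_combo.transition_model()
        exact = rt.cohort_expectation(combo, tm, vals, rt.ModelConfig())
        errs = {}
        for n in (500, 5000):
            errs[n] = np.mean([
                abs(rt.simulate_cohort(
                    combo, tm, vals,
                    rt.ModelConfig(seed=41 + rep, n_patients=n)
                ).mean_qaly - exact.mean_qaly)
                for rep in range(10)
            ])
        # mean absolute error should shrink roughly like 1/sqrt(n)
        assert errs[5000] < errs[500]


class TestCohortExpectation:
    def test_identity_remission_closed_form(self, step_up, truth_su, tariff):
        vals = truth_su.state_values(tariff)
        cfg = rt.ModelConfig(initial_state_distribution=(1, 0, 0, 0))
        res = rt.cohort_expectation(step_up, _identity_tm(step_up), vals, cfg)
        u_rem = vals.utilities[rt.HealthState.REMISSION]
        expected = sum(u_rem * 0.25 * 1.015 ** (-0.25 * k) for k in range(20))
        assert res.mean_qaly == pytest.approx(expected, abs=1e-12)

    def test_uniform_rows_hand_propagation(self, step_up):
        """Two cycles with uniform transition rows, zero drug cost: cycle-0
        cost is the half-cycle mean of the initial and uniform state-cost
        expectations; cycle-1 cost is the uniform expectation, discounted."""
        tm = rt.TransitionModel.from_probs(
            {k: np.full((4, 4), 0.25) for k in step_up.transition_keys})
        costs = [100.0, 200.0, 400.0, 800.0]
        vals = rt.StateValues(
            utilities={s: 0.0 for s in rt.HealthState},
            sick_days_per_cycle={s: 0.0 for s in rt.HealthState},
            hc_cost_per_cycle=dict(zip(rt.HealthState, costs)),
        )
        free = rt.build_strategy({
            "name": "freedrug",
            "escalation_ladder": [
                {"name": s.name, "drug_cost_per_cycle": 0.0,
                 "transition_key": s.transition_key}
                for s in step_up.escalation_ladder],
            "taper_ladder": [
                {"name": s.name, "drug_cost_per_cycle": 0.0,
                 "transition_key": s.transition_key}
                for s in step_up.taper_ladder],
        })
        cfg = rt.ModelConfig(horizon_cycles=2,
                             initial_state_distribution=(0, 0, 1, 0))
        res = rt.cohort_expectation(free, tm, vals, cfg)
        mean_uniform = np.mean(costs)
        expected = (0.5 * (400.0 + mean_uniform) * 1.0
                    + mean_uniform * 1.04 ** -0.25)
        assert res.mean_cost == pytest.approx(expected, abs=1e-9)

    def test_determinism(self, combo, truth_combo, tariff):
        vals = truth_combo.state_values(tariff)
        tm = truth_combo.transition_model()
        r1 = rt.cohort_expectation(combo, tm, vals, rt.ModelConfig())
        r2 = rt.cohort_expectation(combo, tm, vals, rt.ModelConfig())
        assert r1.mean_cost == r2.mean_cost
        assert np.array_equal(r1.occupancy, r2.occupancy)

    def test_zero_rates_unit_utility_gives_five_qalys(self, step_up,
                                                      truth_su):
        cfg = rt.ModelConfig(discount_rate_cost=0.0,
                             discount_rate_effect=0.0)
        res = rt.cohort_expectation(step_up, truth_su.transition_model(),
                                    _unit_vals(1.0), cfg)
        assert res.mean_qaly == pytest.approx(5.0, abs=1e-12)

    def test_probability_conservation(self, step_up, truth_su, tariff):
        res = rt.cohort_expectation(step_up, truth_su.transition_model(),
                                    truth_su.state_values(tariff),
                                    rt.ModelConfig())
        assert np.allclose(res.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_in_utilities(self, step_up):
        """Raising every utility weakly raises the mean QALY (random
        parameter sets, deterministic engine)."""
        rng = np.random.default_rng(77)
        for _ in range(5):
            tm = random_transition_model(rng, step_up.transition_keys)
            vals = random_state_values(rng)
            cfg = rt.ModelConfig()
            base = rt.cohort_expectation(step_up, tm, vals, cfg).mean_qaly
            bumped = dataclasses.replace(
                vals, utilities={s: u + 0.05
                                 for s, u in vals.utilities.items()})
            up = rt.cohort_expectation(step_up, tm, bumped, cfg).mean_qaly
            assert up >= base

    def test_state_space_guard(self, truth_su):
        deep = rt.build_strategy({
            "name": "deep",
            "escalation_ladder": [
                {"name": f"d{i}", "drug_cost_per_cycle": 0,
                 "transition_key": f"d{i}"} for i in range(60)],
            "taper_ladder": [
                {"name": "free", "drug_cost_per_cycle": 0,
                 "transition_key": "free"}],
            "sustained_remission_cycles": 500,
        })
        tm = rt.TransitionModel.from_probs(
            {k: np.eye(4) for k in deep.transition_keys})
        with pytest.raises(ValueError, match="state space"):
            rt.cohort_expectation(deep, tm, _unit_vals(), rt.ModelConfig())
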