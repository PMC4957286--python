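import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reference_model import simulate_stratum

from pacea.arms import ArmSpec, Stratum, build_arms
from pacea.lifetable import LifeTable
from pacea.markov import (HealthState, annual_rate_to_monthly_prob,
                          build_transition_row, cycle_cost,
                          incidence_probability, run_cohort, state_utility)
from pacea.params import Param, set_value


def _flat_life_table(q, share=0.3, min_age=25, max_age=120):
    ages = np.arange(min_age, max_age + 1)
    return LifeTable(ages=ages, q_month=np.full(len(ages), q),
                     cvd_share=np.full(len(ages), share))


def _deathless_utopia(mp, max_age=50):
    """No disease, no mortality, full utility, no discounting."""
    out = mp
    for path, p in [(f"diseases.{d}.incidence.{i}", None)
                    for d in ("chd", "stroke", "diabetes") for i in range(6)]:
        out = set_value(out, path, 0.0)
    for i in range(5):
        out = set_value(out, f"utilities.age_bands.{i}", 1.0)
    out = set_value(out, "utilities.mh_gain_moderate", 0.0)
    out = set_value(out, "utilities.mh_gain_high", 0.0)
    out = dataclasses.replace(out, settings=dataclasses.replace(
        out.settings, annual_discount_rate=0.0, max_age=max_age))
    return out


class TestRateConversion:
    def test_zero_rate_zero_probability(self):
        assert annual_rate_to_monthly_prob(0.0) == 0.0

    def test_closed_form(self):
        assert annual_rate_to_monthly_prob(0.002095) == pytest.approx(
            1 - math.exp(-0.002095 / 12), rel=1e-12)

    @given(r=st.floats(1e-6, 5.0))
    def test_below_naive_division(self, r):
        assert 0 < annual_rate_to_monthly_prob(r) < r / 12

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            annual_rate_to_monthly_prob(-0.1)


class TestIncidenceProbability:
    def test_low_activity_is_baseline(self, mp):
        base = annual_rate_to_monthly_prob(0.002095)
        assert incidence_probability("chd", 50, "low", mp) == pytest.approx(base)

    @pytest.mark.parametrize("disease, level, rr", [
        ("chd", "moderate", 0.90), ("stroke", "high", 0.74),
        ("diabetes", "moderate", 0.67)])
    def test_relative_risk_scaling(self, mp, disease, level, rr):
        low = incidence_probability(disease, 50, "low", mp)
        assert incidence_probability(disease, 50, level, mp) == pytest.approx(low * rr)


class TestTransitionRows:
    @pytest.mark.parametrize("state", [
        HealthState("healthy"), HealthState("chd", 3), HealthState("chd", 20),
        HealthState("stroke", 0), HealthState("diabetes"), HealthState("dead")])
    @pytest.mark.parametrize("age", [35, 45, 70, 95])
    def test_rows_are_stochastic(self, mp, lt, state, age):
        row = build_transition_row(state, age, "moderate", mp, lt)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in row.values())

    def test_dead_is_absorbing(self, mp, lt):
        row = build_transition_row(HealthState("dead"), 60, "low", mp, lt)
        assert row["dead"] == 1.0 and sum(row.values()) == 1.0

    def test_fatal_share_splits_chd_incidence(self, mp, lt):
        row, ex = build_transition_row(HealthState("healthy"), 45, "low", mp, lt,
                                       detail=True)
        p_chd = incidence_probability("chd", 45, "low", mp)
        assert ex["dead_via_chd"] == pytest.approx(p_chd * 0.0877, rel=1e-12)
        assert row["chd"] == pytest.approx(p_chd * (1 - 0.0877), rel=1e-12)

    def test_no_transitions_between_disease_states(self, mp, lt):
        row = build_transition_row(HealthState("stroke", 5), 60, "low", mp, lt)
        assert row["chd"] == 0.0 and row["diabetes"] == 0.0 and row["healthy"] == 0.0


class TestStateUtility:
    def test_healthy_low_activity_is_age_utility(self, mp):
        assert state_utility(HealthState("healthy"), 50, "low", mp) == 0.86

    def test_disease_weight_multiplies_age_utility(self, mp):
        u = state_utility(HealthState("chd", 13), 50, "low", mp)
        assert u == pytest.approx(0.86 * 0.92)
        u_first = state_utility(HealthState("chd", 5), 50, "low", mp)
        assert u_first == pytest.approx(0.86 * 0.80)

    def test_mental_health_gain_clamped_at_full_health(self, mp):
        assert state_utility(HealthState("healthy"), 40, "high", mp) == 1.0

    def test_dead_has_zero_utility(self, mp):
        assert state_utility(HealthState("dead"), 50, "high", mp) == 0.0


class TestCycleCost:
    def test_healthy_and_dead_cost_nothing(self, mp):
        assert cycle_cost(HealthState("healthy"), False, mp) == 0.0
        assert cycle_cost(HealthState("dead"), False, mp) == 0.0

    def test_diabetes_monthly_state_cost(self, mp):
        assert cycle_cost(HealthState("diabetes"), False, mp) == pytest.approx(955 / 12)

    def test_stroke_incidence_cycle_charges_acute_cost(self, mp):
        assert cycle_cost(HealthState("stroke", 0), True, mp) == 10698.0
        assert cycle_cost(HealthState("diabetes"), True, mp) == 0.0


class TestRunCohort:
    def test_deathless_undiscounted_cohort_accrues_horizon(self, mp):
        utopia = _deathless_utopia(mp, max_age=50)
        lt0 = _flat_life_table(0.0)
        arm = ArmSpec("control", (Stratum(1.0, "low", "low"),), 0.0)
        res = run_cohort(arm, utopia, lt0)
        assert res.discounted_qaly == pytest.approx(5.0, abs=1e-9)
        assert res.life_years == pytest.approx(5.0, abs=1e-9)
        assert res.discounted_cost == 0.0

    def test_two_state_toy_matches_geometric_closed_form(self, mp):
        # constant monthly hazard, no disease: discounted life-years are a
        # finite geometric sum sum_t ((1-q) * delta)^t / 12
        q = 0.01
        utopia = _deathless_utopia(mp, max_age=65)
        utopia = dataclasses.replace(utopia, settings=dataclasses.replace(
            utopia.settings, annual_discount_rate=0.035))
        lt_q = _flat_life_table(q, share=0.0)
        arm = ArmSpec("control", (Stratum(1.0, "low", "low"),), 0.0)
        res = run_cohort(arm, utopia, lt_q)
        delta = 1.035 ** (-1 / 12)
        n = (65 - 45) * 12
        x = (1 - q) * delta
        expected = (1 - x ** n) / (1 - x) / 12
        assert res.discounted_life_years == pytest.approx(expected, abs=1e-10)
        assert res.discounted_qaly <= res.discounted_life_years

    def test_discounting_shrinks_totals(self, mp, lt, short_horizon):
        arm = ArmSpec("control", (Stratum(1.0, "low", "low"),), 0.0)
        undisc = dataclasses.replace(short_horizon, settings=dataclasses.replace(
            short_horizon.settings, annual_discount_rate=0.0))
        r0 = run_cohort(arm, undisc, lt)
        r35 = run_cohort(arm, short_horizon, lt)
        assert r35.discounted_qaly < r0.discounted_qaly
        assert r35.discounted_cost < r0.discounted_cost
        assert r35.life_years == pytest.approx(r0.life_years, abs=1e-12)

    def test_engine_matches_reference_simulator(self, mp, lt, short_horizon):
        # dictionary-based oracle built only from the scalar per-state ops
        for before, after in (("high", "low"), ("moderate", "moderate")):
            arm = ArmSpec("x", (Stratum(1.0, before, after),), 0.0)
            res = run_cohort(arm, short_horizon, lt)
            cost, qaly, ly, lyd = simulate_stratum(
                short_horizon, lt, before, after,
                short_horizon.programme.duration_of_effect_months.value)
            assert res.discounted_cost == pytest.approx(cost, abs=1e-9)
            assert res.discounted_qaly == pytest.approx(qaly, abs=1e-12)
            assert res.life_years == pytest.approx(ly, abs=1e-12)
            assert res.discounted_life_years == pytest.approx(lyd, abs=1e-12)

    def test_trace_occupancy_conserved_each_cycle(self, lt, short_horizon):
        intervention, _ = build_arms(short_horizon.programme)
        res = run_cohort(intervention, short_horizon, lt, trace=True)
        sums = res.trace.groupby(["cycle", "stratum"])["occupancy"].sum()
        assert np.allclose(sums.values, 1.0, atol=1e-10)

    def test_raising_incidence_never_raises_qalys(self, mp, lt, short_horizon):
        arm = ArmSpec("control", (Stratum(1.0, "low", "low"),), 0.0)
        base = run_cohort(arm, short_horizon, lt)
        bumped = short_horizon
        for i in range(6):
            bumped = set_value(bumped, f"diseases.stroke.incidence.{i}",
                               bumped.stroke.incidence.bands[i].param.value * 3)
        worse = run_cohort(arm, bumped, lt)
        assert worse.discounted_qaly < base.discounted_qaly

    def test_longer_duration_never_lowers_intervention_qalys(self, lt, short_horizon):
        vals = []
        for months in (4, 12, 20):
            mp2 = set_value(short_horizon, "programme.duration_of_effect_months",
                            float(months))
            intervention, _ = build_arms(mp2.programme)
            vals.append(run_cohort(intervention, mp2, lt).discounted_qaly)
        assert vals[0] <= vals[1] <= vals[2]

    def test_null_effect_isolates_upfront_cost(self, mp, lt, short_horizon):
        # zero mental-health gain + identical activity distributions:
        # arms differ by exactly the programme cost, and by no QALYs
        mp2 = set_value(short_horizon, "utilities.mh_gain_moderate", 0.0)
        mp2 = set_value(mp2, "utilities.mh_gain_high", 0.0)
        mp2 = dataclasses.replace(mp2, programme=dataclasses.replace(
            mp2.programme, followup_activity=mp2.programme.baseline_activity))
        intervention, control = build_arms(mp2.programme)
        r_int = run_cohort(intervention, mp2, lt)
        r_ctl = run_cohort(control, mp2, lt)
        # the product coupling mixes pathways, so equality is exact only in
        # distribution; path dependence of disease risk leaves ~1e-7 residue
        assert r_int.discounted_qaly == pytest.approx(r_ctl.discounted_qaly, abs=1e-6)
        assert r_int.discounted_cost - r_ctl.discounted_cost == pytest.approx(
            intervention.upfront_cost_per_person, abs=1e-3)
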