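import math

import numpy as np
import pytest

import pacea.params as P
from pacea.markov import run_incremental_batch
from pacea.sensitivity import (CEACCurve, PSASample, ceac, evaluate_cea,
                               integer_threshold_search, one_way_sweep,
                               probability_cost_effective, run_psa,
                               sample_parameter_set, threshold_search)


class TestOneWay:
    def test_sweep_at_base_value_reproduces_base_case(self, short_horizon, lt):
        base_cea = evaluate_cea(short_horizon, lt)
        [(v, cea)] = one_way_sweep("utilities.mh_gain_high", [0.104],
                                   short_horizon, lt)
        assert v == 0.104
        assert cea.delta_qaly == pytest.approx(base_cea.delta_qaly, rel=1e-12)
        assert cea.icer == pytest.approx(base_cea.icer, rel=1e-12)

    def test_grid_value_outside_range_rejected(self, short_horizon, lt):
        with pytest.raises(ValueError):
            one_way_sweep("utilities.mh_gain_high", [0.5], short_horizon, lt)

    def test_icer_nonincreasing_in_duration(self, mp, lt):
        sweep = one_way_sweep("programme.duration_of_effect_months",
                              [4, 8, 12, 16, 20], mp, lt)
        icers = [cea.icer for _, cea in sweep]
        assert all(a >= b for a, b in zip(icers, icers[1:]))

    def test_icer_nonincreasing_in_high_activity_mh_gain(self, mp, lt):
        sweep = one_way_sweep("utilities.mh_gain_high",
                              [0.05, 0.104, 0.15, 0.2], mp, lt)
        icers = [cea.icer for _, cea in sweep]
        assert all(a >= b for a, b in zip(icers, icers[1:]))


class TestThresholdSearch:
    def test_unknown_parameter_rejected(self, mp, lt):
        with pytest.raises(P.ParameterError):
            threshold_search("programme.bogus", 20000.0, mp, lt)

    def test_no_crossing_returns_none(self, mp, lt):
        # post-stroke mortality barely moves the ICER over its range
        assert threshold_search("mortality_rrs.stroke.non_cvd", 20000.0,
                                mp, lt) is None

    def test_completion_threshold_agrees_with_grid_scan(self, mp, lt):
        th = threshold_search("programme.completion", 20000.0, mp, lt, tol=1e-4)
        param = P.get_param(mp, "programme.completion")
        grid = np.linspace(param.lower, param.upper, 200)
        mps = [P.set_value(mp, "programme.completion", v) for v in grid]
        inc = run_incremental_batch(mps, lt)
        nmb = 20000.0 * inc["delta_qaly"].values - inc["delta_cost"].values
        crossings = np.flatnonzero(np.diff(np.sign(nmb)))
        assert len(crossings) == 1
        step = grid[1] - grid[0]
        assert abs(th - grid[crossings[0]]) <= step

    def test_integer_duration_threshold_is_first_cost_effective_month(self, mp, lt):
        th = integer_threshold_search("programme.duration_of_effect_months",
                                      20000.0, mp, lt)
        assert isinstance(th, int)
        above = evaluate_cea(P.set_value(mp, "programme.duration_of_effect_months",
                                         float(th - 1)), lt)
        below = evaluate_cea(P.set_value(mp, "programme.duration_of_effect_months",
                                         float(th)), lt)
        assert above.icer > 20000.0 > below.icer


class TestSampler:
    def test_activity_draws_stay_on_simplex(self, mp):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = sample_parameter_set(mp, rng)
            assert sum(s.programme.baseline_activity.fractions) == pytest.approx(1.0)
            assert sum(s.programme.followup_activity.fractions) == pytest.approx(1.0)

    def test_beta_completion_mean_matches_base(self, mp):
        rng = np.random.default_rng(11)
        draws = np.array([sample_parameter_set(mp, rng).programme.completion.value
                          for _ in range(2000)])
        sd = (0.5 - 0.01) / 3.92
        se = sd / math.sqrt(len(draws))
        assert abs(draws.mean() - 159 / 1025) < 3 * se

    def test_lognormal_rr_median_matches_base(self, mp):
        rng = np.random.default_rng(13)
        draws = np.array([
            sample_parameter_set(mp, rng).relative_risks.chd.moderate.value
            for _ in range(2000)])
        assert np.median(draws) == pytest.approx(0.90, abs=0.01)

    def test_draws_respect_distribution_supports(self, mp):
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = sample_parameter_set(mp, rng)
            assert 0 <= s.programme.completion.value <= 1
            for i in range(5):
                assert 0 <= s.utilities.age_bands.bands[i].param.value <= 1
            for d in ("chd", "stroke", "diabetes"):
                assert s.relative_risks.for_disease(d).moderate.value > 0
                assert s.disease(d).annual_state_cost.value >= 0
                for band in s.disease(d).incidence.bands:
                    assert 0 <= band.param.value <= 1
            assert 25 <= s.settings.starting_age.value <= 65
            assert s.settings.starting_age.value == int(s.settings.starting_age.value)
            assert 4 <= s.programme.duration_of_effect_months.value <= 20


class TestPSA:
    def test_same_seed_reproduces_sample_list(self, mp, lt):
        a = run_psa(30, seed=42, base=mp, lt=lt)
        b = run_psa(30, seed=42, base=mp, lt=lt)
        assert [(s.delta_cost, s.delta_qaly) for s in a] == \
            [(s.delta_cost, s.delta_qaly) for s in b]

    def test_results_independent_of_chunking(self, mp, lt):
        a = run_psa(23, seed=9, base=mp, lt=lt, chunk_size=23)
        b = run_psa(23, seed=9, base=mp, lt=lt, chunk_size=5)
        for x, y in zip(a, b):
            assert x.delta_cost == pytest.approx(y.delta_cost, rel=1e-12)
            assert x.delta_qaly == pytest.approx(y.delta_qaly, rel=1e-12)

    def test_ceac_at_base_icer_is_moderate(self, mp, lt):
        # draws should straddle the base case at the base-case ICER
        samples = run_psa(400, seed=3, base=mp, lt=lt)
        base_icer = evaluate_cea(mp, lt).icer
        p = probability_cost_effective(samples, base_icer)
        assert 0.2 <= p <= 0.8


class TestCEAC:
    def _samples(self, rows):
        return [PSASample(i, {}, dc, dq, None) for i, (dc, dq) in enumerate(rows)]

    def test_probability_at_zero_wtp_is_fraction_cost_saving(self):
        s = self._samples([(-10, 0.1), (5, 0.2), (3, -0.1), (-2, -0.5)])
        curve = ceac(s, [0.0])
        assert curve.probability[0] == pytest.approx(0.5)

    def test_single_always_beneficial_sample_gives_unit_curve(self):
        s = self._samples([(-10, 0.1)])
        curve = ceac(s, [0, 10000, 50000])
        assert np.all(curve.probability == 1.0)

    def test_curve_nondecreasing_when_all_draws_gain_qalys(self):
        rng = np.random.default_rng(1)
        s = self._samples([(float(rng.normal(60, 20)), float(rng.uniform(0.0001, 0.01)))
                           for _ in range(200)])
        curve = ceac(s, np.linspace(0, 50000, 26))
        assert np.all(np.diff(curve.probability) >= 0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac([], [20000.0])
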