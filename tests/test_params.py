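import math

import pytest
import yaml
from hypothesis import given, strategies as st

from pacea.params import (ParameterError, load_default_parameters, load_parameters,
                          mental_health_gain, serialize_parameters, get_param,
                          set_value, iter_scalar_params)


class TestBundledDocument:
    def test_base_case_values_load(self, mp):
        assert mp.programme.completion.value == pytest.approx(159 / 1025)
        assert mp.relative_risks.chd.moderate.value == 0.90
        assert mp.settings.annual_discount_rate == 0.035
        assert mp.settings.starting_age.value == 45
        assert mp.chd.incidence.value(50) == 0.002095
        assert mp.stroke.fatal_fraction.value(45) == 0.2346
        assert mp.utilities.age_bands.value(50) == 0.86

    def test_followup_fractions_renormalized_to_simplex(self, mp):
        # printed 23.5/23.5/52.9 sum to 0.999; loader renormalizes proportionally
        fracs = mp.programme.followup_activity.fractions
        assert sum(fracs) == pytest.approx(1.0, abs=1e-12)
        assert fracs[2] / fracs[1] == pytest.approx(52.9 / 23.5, rel=1e-9)

    def test_round_trip_preserves_every_scalar(self, mp):
        mp2 = load_parameters(serialize_parameters(mp))
        for (p1, v1), (p2, v2) in zip(iter_scalar_params(mp), iter_scalar_params(mp2)):
            assert p1 == p2
            assert v1 == v2
        # serialization is a fixed point
        assert serialize_parameters(mp2) == serialize_parameters(mp)

    def test_age_band_lookup_clamps_both_ends(self, mp):
        bands = mp.chd.incidence
        assert bands.value(20) == bands.value(33)
        assert bands.value(95) == bands.value(81)


class TestValidation:
    def _doc(self):
        from importlib import resources
        return yaml.safe_load(
            resources.files("pacea.data").joinpath("base_case.yaml").read_text())

    def _load(self, doc):
        return load_parameters(yaml.safe_dump(doc))

    def test_unnormalized_activity_fractions_rejected(self):
        doc = self._doc()
        doc["programme"]["baseline_activity"]["low"]["value"] = 0.224  # sum 0.9
        with pytest.raises(ParameterError, match="baseline_activity"):
            self._load(doc)

    def test_lower_bound_above_base_rejected(self):
        doc = self._doc()
        doc["relative_risks"]["chd"]["moderate"]["lower"] = 0.95  # base 0.90
        with pytest.raises(ParameterError, match="chd.moderate"):
            self._load(doc)

    def test_unknown_key_rejected(self):
        doc = self._doc()
        doc["programme"]["typo_key"] = 1
        with pytest.raises(ParameterError, match="typo_key"):
            self._load(doc)

    def test_unknown_distribution_rejected(self):
        doc = self._doc()
        doc["utilities"]["diabetes"]["dist"] = "weibull"
        with pytest.raises(ParameterError, match="weibull"):
            self._load(doc)

    def test_missing_section_rejected(self):
        doc = self._doc()
        del doc["mortality_rrs"]
        with pytest.raises(ParameterError, match="mortality_rrs"):
            self._load(doc)

    def test_dropout_ledger_must_account_for_recruits(self):
        doc = self._doc()
        doc["programme"]["dropout_counts"]["month_1"] = 281
        with pytest.raises(ParameterError, match="recruit"):
            self._load(doc)


class TestMentalHealthGain:
    @pytest.mark.parametrize("hours, expected_rounded", [
        (1.0, 0.023), (4.5, 0.104)])
    def test_reproduces_printed_gains(self, mp, hours, expected_rounded):
        g = mental_health_gain(hours, mp.utilities.per_halfhour_gain)
        assert round(g, 3) == expected_rounded

    def test_no_extra_activity_no_gain(self):
        assert mental_health_gain(0.0, 0.000222433333) == 0.0

    def test_negative_hours_rejected(self):
        with pytest.raises(ValueError):
            mental_health_gain(-1.0, 0.0002)

    @given(h=st.floats(0, 20), k=st.floats(0, 0.001))
    def test_linear_in_hours(self, h, k):
        assert mental_health_gain(2 * h, k) == pytest.approx(
            2 * mental_health_gain(h, k), nan_ok=False)


class TestParamRegistry:
    def test_every_registered_scalar_is_settable(self, mp):
        for path, param in iter_scalar_params(mp):
            mp2 = set_value(mp, path, param.value)
            assert get_param(mp2, path).value == pytest.approx(param.value)

    def test_unknown_path_rejected(self, mp):
        with pytest.raises(ParameterError):
            set_value(mp, "programme.nonexistent", 1.0)

    def test_activity_fraction_sweep_trades_against_low_pool(self, mp):
        mp2 = set_value(mp, "programme.baseline_activity.moderate", 0.30)
        fracs = mp2.programme.baseline_activity.fractions
        assert sum(fracs) == pytest.approx(1.0, abs=1e-12)
        assert fracs[1] == pytest.approx(0.30)
        assert fracs[2] == pytest.approx(0.300)   # high untouched
        assert fracs[0] == pytest.approx(0.324 + 0.076)  # low absorbs

    def test_low_fraction_sweep_renormalizes_active_levels(self, mp):
        mp3 = mp.programme.baseline_activity.with_fraction("low", 0.5)
        assert sum(mp3.fractions) == pytest.approx(1.0, abs=1e-12)
        assert mp3.moderate.value / mp3.high.value == pytest.approx(
            0.376 / 0.300, rel=1e-9)

    def test_sampled_value_outside_printed_range_is_accepted(self, mp):
        mp2 = set_value(mp, "relative_risks.chd.moderate", 0.80)  # below lower 0.83
        assert mp2.relative_risks.chd.moderate.value == 0.80
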