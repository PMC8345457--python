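"""Dose-response derivation, clamped evaluation and rate combination."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lagopop.effects import (EndpointInputs, LinearDoseResponse,
                             PesticideToxicityProfile, combine_mortality,
                             combine_reproduction, derive_acute_dr,
                             derive_chronic_dr, effective_rates_for_month,
                             evaluate_dr, round_half_up)
from lagopop.errors import (ConfigurationError, DerivationError, DomainError)
from lagopop.exposure import ExposureSeries


GLYPHOSATE_ACUTE = EndpointInputs(ld0=200, ld50=2000)
GLYPHOSATE_CHRONIC = EndpointInputs(noael=50, loael=175,
                                    interspecies_factor_chronic=5)
BROMOXYNIL_ACUTE = EndpointInputs(ld0=10, ld50=130,
                                  interspecies_factor_acute_ld50=5)
BROMOXYNIL_CHRONIC = EndpointInputs(loael=17.1, interspecies_factor_chronic=5)
BROMOXYNIL_REPRO = EndpointInputs(loael=12.5, interspecies_factor_chronic=5)


class TestAcuteDerivation:
    def test_glyphosate_line(self):
        dr = derive_acute_dr(GLYPHOSATE_ACUTE)
        assert round_half_up(dr.slope, 6) == 0.000278
        assert round_half_up(dr.intercept, 6) == -0.055556

    def test_bromoxynil_line_factor_on_ld50_only(self):
        dr = derive_acute_dr(BROMOXYNIL_ACUTE)
        # anchors (10, 0) and (130/5 = 26, 0.5)
        assert dr(10.0) == 0.0
        assert dr(26.0) == pytest.approx(0.5)
        assert round_half_up(dr.slope, 4) == 0.0313
        assert round_half_up(dr.intercept, 4) == -0.3125

    def test_absent_ld0_means_zero_threshold(self):
        dr = derive_acute_dr(EndpointInputs(ld50=100))
        assert dr.slope == pytest.approx(0.005)
        assert dr.intercept == 0.0

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(DerivationError):
            derive_acute_dr(EndpointInputs(
                ld0=100, ld50=600,
                interspecies_factor_acute_ld50=6))  # adjusted LD50 == LD0


class TestChronicDerivation:
    def test_glyphosate_slope(self):
        der = derive_chronic_dr(GLYPHOSATE_CHRONIC)
        assert round_half_up(der.dose_response.slope, 4) == 0.0071
        assert der.dose_response.intercept == 0.0

    def test_glyphosate_noael_effect_inside_band(self):
        der = derive_chronic_dr(GLYPHOSATE_CHRONIC)
        # effect at adjusted NOAEL 50/5 = 10 must lie inside [0.05, 0.10]
        assert der.noael_effect == pytest.approx(0.25 / 35 * 10)
        assert der.noael_within_band is True

    def test_bromoxynil_chronic_slope(self):
        der = derive_chronic_dr(BROMOXYNIL_CHRONIC)
        assert round_half_up(der.dose_response.slope, 4) == 0.0731

    def test_bromoxynil_reproduction_slope(self):
        der = derive_chronic_dr(BROMOXYNIL_REPRO)
        assert der.dose_response.slope == pytest.approx(0.1)

    def test_effect_at_adjusted_loael_is_default_25_percent(self):
        for inputs in (GLYPHOSATE_CHRONIC, BROMOXYNIL_CHRONIC, BROMOXYNIL_REPRO):
            der = derive_chronic_dr(inputs)
            adj = inputs.loael / inputs.interspecies_factor_chronic
            assert der.dose_response(adj) == pytest.approx(0.25)

    def test_missing_loael_rejected(self):
        with pytest.raises(DerivationError):
            derive_chronic_dr(EndpointInputs(noael=50))


class TestEvaluate:
    def test_below_threshold_clamps_to_zero(self):
        dr = derive_acute_dr(GLYPHOSATE_ACUTE)
        # raw value at ETE 100 is negative (-0.0278)
        assert dr.slope * 100 + dr.intercept < 0
        assert evaluate_dr(dr, 100.0) == 0.0

    def test_anchor_points_exact(self):
        dr = derive_acute_dr(GLYPHOSATE_ACUTE)
        assert evaluate_dr(dr, 200.0) == pytest.approx(0.0, abs=1e-15)
        assert evaluate_dr(dr, 2000.0) == pytest.approx(0.5)

    def test_upper_clamp(self):
        assert evaluate_dr(LinearDoseResponse(1.0, 0.0), 5.0) == 1.0

    def test_negative_exposure_rejected(self):
        with pytest.raises(DomainError):
            evaluate_dr(LinearDoseResponse(1.0), -1.0)

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    def test_monotone_non_decreasing(self, a, b):
        dr = derive_acute_dr(BROMOXYNIL_ACUTE)
        lo, hi = sorted((a, b))
        assert evaluate_dr(dr, lo) <= evaluate_dr(dr, hi)


def mortality_by_inclusion_exclusion(rates):
    """Independent competing risks: P(die) via inclusion-exclusion."""
    total = 0.0
    for k in range(1, len(rates) + 1):
        for subset in itertools.combinations(rates, k):
            total += (-1) ** (k + 1) * np.prod(subset)
    return total


class TestCombineMortality:
    @pytest.mark.parametrize("bg,rates,expected", [
        (0.11, [0.25], 0.3325),       # 1 - 0.89*0.75
        (0.11, [], 0.11),
        (0.0, [0.5, 0.5], 0.75),      # 1 - 0.25
    ])
    def test_examples(self, bg, rates, expected):
        assert combine_mortality(bg, rates) == pytest.approx(expected)

    def test_matches_inclusion_exclusion_on_grid(self):
        grid = [0.0, 0.1, 0.25, 0.5, 0.9, 1.0]
        for n in (1, 2, 3):
            for combo in itertools.product(grid, repeat=n + 1):
                bg, rates = combo[0], list(combo[1:])
                expected = mortality_by_inclusion_exclusion([bg] + rates)
                assert combine_mortality(bg, rates) == pytest.approx(
                    expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1), max_size=4), st.floats(0, 1))
    def test_symmetric_bounded_and_absorbing(self, rates, bg):
        v = combine_mortality(bg, rates)
        assert 0.0 <= v <= 1.0
        assert combine_mortality(bg, list(reversed(rates))) == pytest.approx(v)
        assert combine_mortality(bg, rates + [1.0]) == 1.0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_each_argument(self, bg, r, delta):
        hi = min(1.0, r + delta)
        assert combine_mortality(bg, [r]) <= combine_mortality(bg, [hi])

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            combine_mortality(1.2, [])
        with pytest.raises(DomainError):
            combine_mortality(0.1, [-0.2])


class TestCombineReproduction:
    @pytest.mark.parametrize("bg,effects,expected", [
        (4.0, [0.25], 3.0),
        (4.0, [], 4.0),
        (1.75, [0.1, 0.5], 0.7875),
    ])
    def test_examples(self, bg, effects, expected):
        assert combine_reproduction(bg, effects) == pytest.approx(expected)

    @given(st.floats(0, 10), st.lists(st.floats(0, 1), max_size=3))
    def test_monotone_non_increasing_and_zero_conditions(self, bg, effects):
        v = combine_reproduction(bg, effects)
        assert v <= bg + 1e-12
        if bg == 0 or any(e == 1.0 for e in effects):
            assert v == 0.0
        assert combine_reproduction(bg, effects + [0.5]) <= v + 1e-12


def spike_series(month, value, window=5, n_months=6, days_per_month=30):
    """Exposure whose TWA (at the given window) is confined to one month:
    the pulse stops window-1 days before the month boundary so the running
    mean does not spill into the next block."""
    ete = np.zeros(n_months * days_per_month)
    lo = month * days_per_month
    ete[lo:lo + days_per_month - (window - 1)] = value
    return ExposureSeries("n", "p", ete)


def profile(window=5, repro_lags=(1, 2)):
    return PesticideToxicityProfile(
        pesticide="p",
        chronic=LinearDoseResponse(0.05), chronic_twa_window_days=window,
        reproduction=LinearDoseResponse(0.1),
        reproduction_twa_window_days=window,
        reproduction_lag_months=repro_lags)


class TestEffectiveRatesForMonth:
    BG_M = [0.77, 0.38, 0.11, 0.11]
    BG_R = [0.0, 0.0, 0.0, 4.0]

    def test_no_pesticides_leaves_background(self):
        m, r = effective_rates_for_month(2, [], {}, self.BG_M, self.BG_R)
        np.testing.assert_allclose(m, self.BG_M)
        np.testing.assert_allclose(r, self.BG_R)

    def test_loael_exposure_gives_25_percent_effect(self):
        # constant exposure at the adjusted LOAEL in the previous month
        prof = PesticideToxicityProfile(
            pesticide="p",
            chronic=derive_chronic_dr(GLYPHOSATE_CHRONIC).dose_response,
            chronic_twa_window_days=12)
        series = {"p": ExposureSeries("n", "p", np.full(90, 35.0))}
        m, _ = effective_rates_for_month(1, [prof], series,
                                         self.BG_M, self.BG_R)
        assert m[3] == pytest.approx(combine_mortality(0.11, [0.25]))

    def test_lag_schedule_hand_traced(self):
        """Exposure confined to month 1: mortality modified only in month 2;
        reproduction in months 2 and 3."""
        series = {"p": spike_series(1, 10.0)}
        prof = profile()
        changed_m, changed_r = [], []
        for month in range(6):
            m, r = effective_rates_for_month(month, [prof], series,
                                             self.BG_M, self.BG_R)
            if not np.allclose(m, self.BG_M):
                changed_m.append(month)
            if not np.allclose(r, self.BG_R):
                changed_r.append(month)
        assert changed_m == [2]
        assert changed_r == [2, 3]

    def test_single_month_pregnancy_variant(self):
        series = {"p": spike_series(1, 10.0)}
        prof = profile(repro_lags=(1,))
        changed_r = [month for month in range(6)
                     if not np.allclose(effective_rates_for_month(
                         month, [prof], series, self.BG_M, self.BG_R)[1],
                         self.BG_R)]
        assert changed_r == [2]

    def test_missing_series_rejected(self):
        with pytest.raises(ConfigurationError):
            effective_rates_for_month(1, [profile()], {},
                                      self.BG_M, self.BG_R)
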