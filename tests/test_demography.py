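"""Daily mortality, reproduction, aging and their statistical expectations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lagopop.demography import (advance_age, assign_groups,
                                daily_mortality_step,
                                daily_reproduction_step, initialize_nest,
                                monthly_to_daily_mortality)
from lagopop.errors import ConfigurationError, DomainError

from conftest import make_nest


class TestMonthlyToDaily:
    @pytest.mark.parametrize("m,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundaries(self, m, expected):
        assert monthly_to_daily_mortality(m, 30) == expected

    def test_known_value(self):
        # 1 - 0.89**(1/30), frozen from the closed form
        assert monthly_to_daily_mortality(0.11, 30) == pytest.approx(
            0.0038768, abs=5e-7)

    @given(st.floats(0, 1), st.integers(1, 120))
    def test_compounding_recovers_monthly_rate(self, m, days):
        d = monthly_to_daily_mortality(m, days)
        assert (1 - d) ** days == pytest.approx(1 - m, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            monthly_to_daily_mortality(1.5, 30)
        with pytest.raises(DomainError):
            monthly_to_daily_mortality(-0.1, 30)


class TestInitializeNest:
    def test_group_sizes_match_config(self):
        cfg = make_nest(initial_counts=(10, 20, 30, 80))
        state = initialize_nest(cfg, 7)
        assert state.size == 140
        assert list(state.counts_by_group()) == [10, 20, 30, 80]
        state.audit()

    def test_degenerate_sex_ratio(self):
        cfg = make_nest(initial_counts=(0, 0, 0, 10), sex_ratio_male=1.0)
        state = initialize_nest(cfg, 0)
        assert state.size == 10
        assert state.sex_male.all()
        assert (state.group == 3).all()

    def test_deterministic_under_seed(self):
        cfg = make_nest()
        a, b = initialize_nest(cfg, 42), initialize_nest(cfg, 42)
        assert np.array_equal(a.age_days, b.age_days)
        assert np.array_equal(a.sex_male, b.sex_male)

    def test_rejects_negative_counts(self):
        with pytest.raises(ConfigurationError):
            make_nest(initial_counts=(-1, 0, 0, 10))


class TestMortalityStep:
    def test_zero_rates_leave_state_unchanged(self, rng):
        state = initialize_nest(make_nest(), 0)
        before = state.size
        deaths = daily_mortality_step(state, [0, 0, 0, 0], rng)
        assert state.size == before and deaths.sum() == 0

    def test_certain_death_empties_nest(self, rng):
        state = initialize_nest(make_nest(), 0)
        deaths = daily_mortality_step(state, [1, 1, 1, 1], rng)
        assert state.size == 0 and deaths.sum() == 20

    def test_binomial_expectation(self):
        # 1000 individuals at daily rate 0.0039: mean deaths ~ 3.9
        total, reps = 0, 500
        for i in range(reps):
            state = initialize_nest(
                make_nest(initial_counts=(0, 0, 0, 1000)), i)
            total += daily_mortality_step(
                state, [0, 0, 0, 0.0039], np.random.default_rng(10_000 + i)).sum()
        assert total / reps == pytest.approx(3.9, abs=0.3)

    def test_rejects_bad_rates(self, rng):
        state = initialize_nest(make_nest(), 0)
        with pytest.raises(DomainError):
            daily_mortality_step(state, [0, 0, 0, 1.2], rng)


class TestReproductionStep:
    def test_out_of_season_no_births(self, rng):
        state = initialize_nest(make_nest(), 0)
        assert daily_reproduction_step(state, [0, 0, 0, 4.0], False, 30,
                                       0.5, rng) == 0

    def test_zero_rate_no_births(self, rng):
        state = initialize_nest(make_nest(), 0)
        assert daily_reproduction_step(state, [0, 0, 0, 0.0], True, 30,
                                       0.5, rng) == 0

    def test_poisson_expectation(self):
        # 100 reproductive females, monthly rate 4, 30-day month: mean 13.3/day
        cfg = make_nest(initial_counts=(0, 0, 0, 100), sex_ratio_male=0.0)
        total, reps = 0, 500
        for i in range(reps):
            state = initialize_nest(cfg, 0)
            total += daily_reproduction_step(
                state, [0, 0, 0, 4.0], True, 30, 0.5,
                np.random.default_rng(20_000 + i))
        assert total / reps == pytest.approx(100 * 4 / 30, abs=0.5)

    def test_newborns_enter_group_zero_at_age_zero(self, rng):
        cfg = make_nest(initial_counts=(0, 0, 0, 50), sex_ratio_male=0.0)
        state = initialize_nest(cfg, 0)
        births = daily_reproduction_step(state, [0, 0, 0, 30.0], True, 30,
                                         0.5, rng)
        assert births > 0
        newborns = state.age_days == 0
        assert newborns.sum() == births
        assert (state.group[newborns] == 0).all()
        state.audit()

    def test_rejects_negative_rate(self, rng):
        state = initialize_nest(make_nest(), 0)
        with pytest.raises(DomainError):
            daily_reproduction_step(state, [0, 0, 0, -1.0], True, 30, 0.5, rng)


class TestAdvanceAge:
    def test_threshold_crossing(self):
        cfg = make_nest(initial_counts=(1, 0, 0, 0))
        state = initialize_nest(cfg, 0)
        state.age_days[:] = 19  # one day below the group-1 threshold
        state.group = assign_groups(state.age_days, cfg.thresholds)
        advance_age(state)
        assert state.group[0] == 1 and state.age_days[0] == 20

    def test_adult_stays_in_last_group(self):
        state = initialize_nest(make_nest(initial_counts=(0, 0, 0, 3)), 0)
        for _ in range(100):
            advance_age(state)
        assert (state.group == 3).all()

    def test_repeated_application_composes(self):
        state_a = initialize_nest(make_nest(), 5)
        state_b = initialize_nest(make_nest(), 5)
        n = 37
        for _ in range(n):
            advance_age(state_a)
        assert np.array_equal(state_a.age_days, state_b.age_days + n)
        state_a.audit()

    @given(st.lists(st.integers(0, 400), min_size=1, max_size=50))
    def test_membership_invariant_for_any_ages(self, ages):
        thresholds = np.array([0, 20, 75, 105])
        groups = assign_groups(np.array(ages), thresholds)
        for age, g in zip(ages, groups):
            assert thresholds[g] <= age
            assert g == 3 or age < thresholds[g + 1]


def test_daily_conservation_of_individuals(rng):
    """individuals(t+1) = individuals(t) - deaths + births, every day."""
    cfg = make_nest(initial_counts=(20, 20, 20, 40))
    state = initialize_nest(cfg, 3)
    daily = [monthly_to_daily_mortality(g.background_monthly_mortality, 30)
             for g in cfg.age_groups]
    for day in range(120):
        before = state.size
        deaths = daily_mortality_step(state, daily, rng).sum()
        births = daily_reproduction_step(state, [0, 0, 0, 4.0], True, 30,
                                         0.5, rng)
        advance_age(state)
        assert state.size == before - deaths + births
        state.audit()
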