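"""Individual-based nest population dynamics.

A *nest* is a localized group of individuals sharing a feeding area and a
common set of demographic parameters: up to four age groups, each with a
background monthly mortality rate, a background monthly reproduction rate
(offspring per reproductive female per month) for the reproductive groups,
and a seasonal reproductive window.  The daily cycle is: allocate deaths at
random within each age group, draw newborns for reproductive females while
the season is open, then age every individual by one day and promote those
crossing an age-group threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "AgeGroupSpec",
    "NestConfig",
    "PopulationState",
    "initialize_nest",
    "monthly_to_daily_mortality",
    "daily_mortality_step",
    "daily_reproduction_step",
    "advance_age",
]

MONTH_NAMES = (
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
)


def month_index(month: int | str) -> int:
    """Normalize a calendar month given by name or 0-based index."""
    if isinstance(month, str):
        name = month.strip().lower()
        if name not in MONTH_NAMES:
            raise ConfigurationError(f"unknown month name: {month!r}")
        return MONTH_NAMES.index(name)
    m = int(month)
    if not 0 <= m <= 11:
        raise ConfigurationError(f"month index out of range: {month}")
    return m


@dataclass(frozen=True)
class AgeGroupSpec:
    """One age group of a nest (e.g. nestling / juvenile / subadult / adult)."""

    index: int
    label: str
    min_age_days: int
    background_monthly_mortality: float
    background_monthly_reproduction: float = 0.0
    reproductive: bool = False

    def __post_init__(self):
        if self.min_age_days < 0:
            raise ConfigurationError(f"group {self.label}: min_age_days < 0")
        if not 0.0 <= self.background_monthly_mortality <= 1.0:
            raise ConfigurationError(
                f"group {self.label}: monthly mortality must be in [0, 1]")
        if self.background_monthly_reproduction < 0:
            raise ConfigurationError(
                f"group {self.label}: monthly reproduction must be >= 0")
        if self.background_monthly_reproduction > 0 and not self.reproductive:
            # a positive reproduction rate implies the group reproduces
            object.__setattr__(self, "reproductive", True)


def validate_age_groups(groups: Sequence[AgeGroupSpec]) -> None:
    if not groups:
        raise ConfigurationError("at least one age group is required")
    if groups[0].min_age_days != 0:
        raise ConfigurationError("first age group must start at age 0")
    for i, g in enumerate(groups):
        if g.index != i:
            raise ConfigurationError("age group indices must be 0..n-1 in order")
        if i and g.min_age_days <= groups[i - 1].min_age_days:
            raise ConfigurationError("min_age_days must be strictly increasing")


@dataclass
class NestConfig:
    """Location, initial structure and demographic parameters of one nest."""

    nest_id: str
    location: tuple[float, float]
    species: str
    age_groups: tuple[AgeGroupSpec, ...]
    initial_counts: tuple[int, ...]
    sex_ratio_male: float = 0.5
    reproductive_season: frozenset[int] = frozenset()
    feeding_radius: float = 250.0
    max_age_days: int | None = None  # upper bound for initial adult ages

    def __post_init__(self):
        self.age_groups = tuple(self.age_groups)
        self.initial_counts = tuple(int(c) for c in self.initial_counts)
        self.reproductive_season = frozenset(
            month_index(m) for m in self.reproductive_season)
        self.validate()

    def validate(self) -> None:
        validate_age_groups(self.age_groups)
        if len(self.initial_counts) != len(self.age_groups):
            raise ConfigurationError(
                f"nest {self.nest_id}: initial_counts must align with age_groups")
        if any(c < 0 for c in self.initial_counts):
            raise ConfigurationError(f"nest {self.nest_id}: negative initial count")
        if sum(self.initial_counts) <= 0:
            raise ConfigurationError(f"nest {self.nest_id}: empty initial population")
        if not 0.0 <= self.sex_ratio_male <= 1.0:
            raise ConfigurationError(f"nest {self.nest_id}: sex_ratio_male not in [0,1]")
        if self.feeding_radius <= 0:
            raise ConfigurationError(f"nest {self.nest_id}: feeding_radius must be > 0")
        if any(g.reproductive for g in self.age_groups) and not self.reproductive_season:
            raise ConfigurationError(
                f"nest {self.nest_id}: reproductive groups need a non-empty season")

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([g.min_age_days for g in self.age_groups], dtype=np.int64)

    @property
    def n_groups(self) -> int:
        return len(self.age_groups)


class PopulationState:
    """Mutable state of one nest: ids, ages, sexes and group membership.

    Individual ids are never reused within a run; dead individuals are simply
    dropped from the arrays.
    """

    __slots__ = ("nest_id", "day", "ids", "age_days", "sex_male", "group",
                 "_next_id", "_thresholds")

    def __init__(self, nest_id: str, thresholds: np.ndarray,
                 ids: np.ndarray, age_days: np.ndarray, sex_male: np.ndarray,
                 day: int = 0, next_id: int | None = None):
        self.nest_id = nest_id
        self.day = day
        self._thresholds = np.asarray(thresholds, dtype=np.int64)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.age_days = np.asarray(age_days, dtype=np.int64)
        self.sex_male = np.asarray(sex_male, dtype=bool)
        self.group = assign_groups(self.age_days, self._thresholds)
        self._next_id = int(next_id if next_id is not None
                            else (self.ids.max() + 1 if self.ids.size else 0))

    @property
    def size(self) -> int:
        return int(self.ids.size)

    def counts_by_group(self) -> np.ndarray:
        return np.bincount(self.group, minlength=len(self._thresholds)).astype(np.int64)

    def take_ids(self, n: int) -> np.ndarray:
        out = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        return out

    def audit(self) -> None:
        """Verify internal invariants; raises AssertionError on violation."""
        assert self.ids.size == np.unique(self.ids).size, "duplicate individual ids"
        assert np.all(self.age_days >= 0)
        expected = assign_groups(self.age_days, self._thresholds)
        assert np.array_equal(self.group, expected), "group membership violated"


def assign_groups(age_days: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Highest group whose entry threshold is <= age."""
    return np.searchsorted(thresholds[1:], age_days, side="right").astype(np.int64)


def initialize_nest(config: NestConfig, rng_seed) -> PopulationState:
    """Create the day-0 population of a nest.

    Ages are drawn uniformly within each group's age span (the last, open-ended
    group spans from its threshold to ``max_age_days``, default threshold +
    365 days); sexes are independent Bernoulli draws with ``sex_ratio_male``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    thresholds = config.thresholds
    spans_hi = list(thresholds[1:]) + [
        config.max_age_days if config.max_age_days is not None
        else int(thresholds[-1]) + 365]
    ages, sexes = [], []
    for g, count in enumerate(config.initial_counts):
        lo, hi = int(thresholds[g]), int(spans_hi[g])
        ages.append(rng.integers(lo, max(hi, lo + 1), size=count))
        sexes.append(rng.random(count) < config.sex_ratio_male)
    age_days = np.concatenate(ages) if ages else np.empty(0, dtype=np.int64)
    sex_male = np.concatenate(sexes) if sexes else np.empty(0, dtype=bool)
    ids = np.arange(age_days.size, dtype=np.int64)
    return PopulationState(config.nest_id, thresholds, ids, age_days, sex_male)


def monthly_to_daily_mortality(m_month: float, days_per_month: int) -> float:
    """Daily mortality whose geometric compounding over a month recovers
    the monthly rate: ``1 - (1 - m)**(1/days_per_month)``."""
    if not 0.0 <= m_month <= 1.0:
        raise DomainError(f"monthly mortality {m_month} outside [0, 1]")
    if days_per_month < 1:
        raise DomainError("days_per_month must be >= 1")
    return 1.0 - (1.0 - m_month) ** (1.0 / days_per_month)


def daily_mortality_step(state: PopulationState,
                         effective_daily_mortality: Sequence[float],
                         rng: np.random.Generator) -> np.ndarray:
    """Apply one day of mortality; returns the death count per age group.

    Per group, the number of deaths is a binomial draw on the group size and
    its daily rate; the dead are then chosen uniformly without replacement.
    The state is modified in place.
    """
    rates = np.asarray(effective_daily_mortality, dtype=float)
    if rates.shape != (len(state._thresholds),):
        raise DomainError("one mortality rate per age group is required")
    if np.any((rates < 0) | (rates > 1)):
        raise DomainError("daily mortality rates must lie in [0, 1]")
    deaths = np.zeros(rates.size, dtype=np.int64)
    if state.size == 0 or not np.any(rates > 0):
        return deaths
    kill_mask = np.zeros(state.size, dtype=bool)
    for g in range(rates.size):
        members = np.flatnonzero(state.group == g)
        if members.size == 0 or rates[g] == 0.0:
            continue
        n_dead = int(rng.binomial(members.size, rates[g]))
        deaths[g] = n_dead
        if n_dead:
            victims = rng.choice(members, size=n_dead, replace=False)
            kill_mask[victims] = True
    if kill_mask.any():
        keep = ~kill_mask
        state.ids = state.ids[keep]
        state.age_days = state.age_days[keep]
        state.sex_male = state.sex_male[keep]
        state.group = state.group[keep]
    return deaths


def daily_reproduction_step(state: PopulationState,
                            effective_monthly_reproduction: Sequence[float],
                            month_in_season: bool,
                            days_per_month: int,
                            sex_ratio_male: float,
                            rng: np.random.Generator) -> int:
    """Apply one day of reproduction; returns the number of newborns.

    Each female in a group with a positive monthly rate contributes newborns
    drawn from a Poisson law with mean ``rate / days_per_month``; newborns
    enter group 0 at age 0 with random sex.  Out of season, no births occur.
    """
    rates = np.asarray(effective_monthly_reproduction, dtype=float)
    if np.any(rates < 0):
        raise DomainError("monthly reproduction rates must be >= 0")
    if not month_in_season or state.size == 0:
        return 0
    births = 0
    female = ~state.sex_male
    for g in np.flatnonzero(rates > 0):
        n_females = int(np.count_nonzero(female & (state.group == g)))
        if n_females:
            births += int(rng.poisson(n_females * rates[g] / days_per_month))
    if births:
        new_ids = state.take_ids(births)
        state.ids = np.concatenate([state.ids, new_ids])
        state.age_days = np.concatenate(
            [state.age_days, np.zeros(births, dtype=np.int64)])
        state.sex_male = np.concatenate(
            [state.sex_male, rng.random(births) < sex_ratio_male])
        state.group = np.concatenate(
            [state.group, np.zeros(births, dtype=np.int64)])
    return births


def advance_age(state: PopulationState,
                age_groups: Sequence[AgeGroupSpec] | None = None) -> None:
    """Age every individual by one day and promote across thresholds."""
    if age_groups is not None:
        thresholds = np.array([g.min_age_days for g in age_groups], dtype=np.int64)
        state._thresholds = thresholds
    state.age_days = state.age_days + 1
    state.group = assign_groups(state.age_days, state._thresholds)
    state.day += 1
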