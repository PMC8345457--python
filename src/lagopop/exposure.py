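"""Daily residues, dietary exposure (ETE) and time-weighted averages.

Residues on a food item after a spray event follow the generic structure of
regulatory dietary-exposure assessments: an initial concentration equal to
RUD x application rate (mg/kg fresh weight per kg a.s./ha) scaled by the
zone's deposition (drift) fraction, then first-order dissipation with
half-life DT50.  Daily exposure per kg body weight is the diet-weighted
residue times the food-intake-rate-to-body-weight ratio (FIR/bw):

    ETE_t = FIR/bw * sum_items fraction_item * residue_item(t)

Time-weighted averages (TWA) over an endpoint-specific window of preceding
days, and their monthly maxima, feed the chronic/reproductive dose-response
functions.  All numeric inputs (RUD, DT50, FIR/bw, drift) are configuration;
no regulatory default values are hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "ApplicationEvent",
    "ResidueParameters",
    "IntakeParameters",
    "ExposureSeries",
    "residue_at",
    "residue_series",
    "daily_ete",
    "twa",
    "twa_series",
    "max_monthly_twa",
]

ZONE_KINDS = ("core", "inner_band", "outer_band", "background")

DEFAULT_DRIFT = {"core": 1.0, "inner_band": 1.0, "outer_band": 0.0,
                 "background": 0.0}


@dataclass(frozen=True)
class ApplicationEvent:
    """One spray event on one field."""

    pesticide: str
    field_id: str
    day: int
    rate: float  # kg a.s./ha
    drift_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIFT))

    def __post_init__(self):
        if self.rate <= 0:
            raise ConfigurationError("application rate must be > 0")
        if self.day < 0:
            raise ConfigurationError("application day must be >= 0")
        merged = dict(DEFAULT_DRIFT)
        merged.update(self.drift_fractions)
        for zone, f in merged.items():
            if zone not in ZONE_KINDS:
                raise ConfigurationError(f"unknown zone kind {zone!r}")
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"drift fraction for {zone} not in [0,1]")
        object.__setattr__(self, "drift_fractions", merged)


@dataclass(frozen=True)
class ResidueParameters:
    """Residue-per-unit-dose and dissipation half-life for one
    (pesticide, food item) pair."""

    pesticide: str
    food_item: str
    rud: float   # mg/kg residue per 1 kg/ha applied
    dt50: float  # days

    def __post_init__(self):
        if self.rud < 0:
            raise ConfigurationError("RUD must be >= 0")
        if self.dt50 <= 0:
            raise ConfigurationError("DT50 must be > 0")


@dataclass(frozen=True)
class IntakeParameters:
    """Food intake rate over body weight for one species (kg/kg bw/day),
    with optional per-age-group multipliers."""

    species: str
    fir_over_bw: float
    group_multipliers: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.fir_over_bw <= 0:
            raise ConfigurationError("FIR/bw must be > 0")
        if self.group_multipliers is not None:
            object.__setattr__(self, "group_multipliers",
                               tuple(float(m) for m in self.group_multipliers))
            if any(m < 0 for m in self.group_multipliers):
                raise ConfigurationError("group multipliers must be >= 0")


@dataclass
class ExposureSeries:
    """Daily estimated theoretical exposure for one nest and pesticide."""

    nest_id: str
    pesticide: str
    daily_ete: np.ndarray  # mg/kg bw/day, one entry per simulated day

    def __post_init__(self):
        self.daily_ete = np.asarray(self.daily_ete, dtype=float)
        if np.any(self.daily_ete < 0):
            raise DomainError("daily ETE must be non-negative")

    @property
    def n_days(self) -> int:
        return int(self.daily_ete.size)


def residue_at(day: int, applications: Iterable[ApplicationEvent],
               params: ResidueParameters, zone: str) -> float:
    """Residue (mg/kg) on a food item in a zone kind at ``day``.

    Superposition over all past applications, each decaying as
    ``2**(-(day - day_app)/DT50)``; zero before the first application.
    """
    if zone not in ZONE_KINDS:
        raise ConfigurationError(f"unknown zone kind {zone!r}")
    if day < 0:
        raise DomainError("day must be >= 0")
    total = 0.0
    for app in applications:
        if app.pesticide != params.pesticide or app.day > day:
            continue
        drift = app.drift_fractions.get(zone, 0.0)
        total += (params.rud * app.rate * drift
                  * 2.0 ** (-(day - app.day) / params.dt50))
    return total


def residue_series(horizon_days: int, applications: Sequence[ApplicationEvent],
                   params: ResidueParameters, zone: str) -> np.ndarray:
    """Vectorized ``residue_at`` over days 0..horizon-1."""
    if zone not in ZONE_KINDS:
        raise ConfigurationError(f"unknown zone kind {zone!r}")
    days = np.arange(horizon_days)
    out = np.zeros(horizon_days)
    for app in applications:
        if app.pesticide != params.pesticide:
            continue
        drift = app.drift_fractions.get(zone, 0.0)
        active = days >= app.day
        out[active] += (params.rud * app.rate * drift
                        * 2.0 ** (-(days[active] - app.day) / params.dt50))
    return out


def daily_ete(diet, residues: Mapping[tuple[str, str], float],
              intake: IntakeParameters) -> float:
    """One day's exposure: FIR/bw times the diet-weighted residue.

    ``diet`` is a DietFractionTable; ``residues`` maps (zone_id, food_item)
    to mg/kg for that day.
    """
    weighted = sum(entry.fraction * residues.get((entry.zone_id, entry.food_item), 0.0)
                   for entry in diet.entries)
    return intake.fir_over_bw * weighted


def twa(series: ExposureSeries, window: int, t: int) -> float:
    """Mean daily ETE over days ``max(0, t-window+1)..t`` (window truncated
    at simulation start)."""
    if window < 1:
        raise ConfigurationError("TWA window must be >= 1 day")
    if t < 0 or t >= series.n_days:
        raise DomainError(f"day {t} outside the simulated range")
    lo = max(0, t - window + 1)
    return float(series.daily_ete[lo:t + 1].mean())


def twa_series(series: ExposureSeries, window: int) -> np.ndarray:
    """TWA at every simulated day (vectorized running mean with truncation)."""
    if window < 1:
        raise ConfigurationError("TWA window must be >= 1 day")
    x = series.daily_ete
    csum = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(x.size)
    lo = np.maximum(0, t - window + 1)
    return (csum[t + 1] - csum[lo]) / (t + 1 - lo)


def max_monthly_twa(series: ExposureSeries, window: int, month_index: int,
                    days_per_month: int = 30) -> float:
    """Maximum TWA over the days of one fixed-length month block."""
    if month_index < 0:
        raise DomainError("month before simulation start")
    lo = month_index * days_per_month
    if lo >= series.n_days:
        raise DomainError(f"month {month_index} not simulated")
    hi = min(series.n_days, lo + days_per_month)
    tw = twa_series(series, window)
    return float(tw[lo:hi].max())
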