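"""Simulation orchestration: daily loop, monthly rate schedule, replication.

The daily cycle within each nest is fixed as:

1. at 30-day month boundaries, recompute the month's effective mortality and
   reproduction rates from the lagged maximum TWA exposures;
2. apply acute mortality driven by the day's ETE (no background acute
   mortality);
3. apply the daily background+chronic mortality (geometric split of the
   effective monthly rate);
4. apply reproduction if the calendar month is inside the season;
5. advance ages and promote across group thresholds.

Replicated runs use seeds ``base_seed + i``; each nest draws from its own
substream derived from (iteration seed, nest id) so adding a nest does not
perturb the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import (NestConfig, PopulationState, advance_age,
                         daily_mortality_step, daily_reproduction_step,
                         initialize_nest, month_index,
                         monthly_to_daily_mortality)
from .effects import (PesticideToxicityProfile, combine_mortality,
                      effective_rates_for_month)
from .errors import ConfigurationError
from .exposure import (ApplicationEvent, ExposureSeries, IntakeParameters,
                       ResidueParameters, residue_series, twa_series)
from .landscape import (BACKGROUND, DietEntry, DietFractionTable, FeedingArea,
                        Landscape, diet_fractions, feeding_zone_overlap,
                        split_zone_id, zone_id)

__all__ = [
    "DietSpec",
    "ScenarioConfig",
    "SimulationResult",
    "ReplicationSummary",
    "validate_config",
    "run",
    "replicate",
    "export",
]


@dataclass(frozen=True)
class DietSpec:
    """How a nest's diet fractions are obtained.

    ``worst_case``: the whole diet comes from one food item in one field's
    core (the maximum-exposure assumption of screening-level assessments).
    ``landscape``: fractions are computed from the feeding-disc overlap with
    the landscape zones, weighted by per-(zone kind, item) food weights.
    """

    mode: Literal["worst_case", "landscape"] = "worst_case"
    field_id: str | None = None
    food_item: str | None = None
    food_weights: Mapping[tuple[str, str], float] | None = None
    resolution: float | None = None


@dataclass
class ScenarioConfig:
    """Full specification of one simulation experiment."""

    name: str
    horizon_days: int
    nests: tuple[NestConfig, ...]
    landscape: Landscape = dc_field(default_factory=Landscape)
    applications: tuple[ApplicationEvent, ...] = ()
    residue_params: tuple[ResidueParameters, ...] = ()
    intake: Mapping[str, IntakeParameters] = dc_field(default_factory=dict)
    toxicity_profiles: tuple[PesticideToxicityProfile, ...] = ()
    diets: Mapping[str, DietSpec] = dc_field(default_factory=dict)
    days_per_month: int = 30
    start_month: int | str = "december"
    iterations: int = 50
    base_seed: int = 0
    summary_mode: Literal["mean_ci95", "min_max"] = "mean_ci95"

    def __post_init__(self):
        self.nests = tuple(self.nests)
        self.applications = tuple(self.applications)
        self.residue_params = tuple(self.residue_params)
        self.toxicity_profiles = tuple(self.toxicity_profiles)
        self.start_month = month_index(self.start_month)

    def calendar_month(self, block: int) -> int:
        return (self.start_month + block) % 12


def validate_config(config: ScenarioConfig) -> list[str]:
    """Collect all configuration violations (empty list when valid)."""
    problems: list[str] = []
    if config.horizon_days < 1:
        problems.append("horizon_days must be >= 1")
    if config.days_per_month < 1:
        problems.append("days_per_month must be >= 1")
    if config.iterations < 1:
        problems.append("iterations must be >= 1")
    if config.summary_mode not in ("mean_ci95", "min_max"):
        problems.append(f"unknown summary_mode {config.summary_mode!r}")
    if config.summary_mode == "mean_ci95" and config.iterations < 2:
        problems.append("mean_ci95 summaries need at least 2 iterations")
    if not config.nests:
        problems.append("at least one nest is required")
    ids = [n.nest_id for n in config.nests]
    if len(set(ids)) != len(ids):
        problems.append("duplicate nest ids")
    field_ids = {f.field_id for f in config.landscape.fields}
    for app in config.applications:
        if app.field_id not in field_ids:
            problems.append(f"application on unknown field {app.field_id!r}")
        if app.day >= config.horizon_days:
            problems.append(
                f"application day {app.day} beyond horizon {config.horizon_days}")
    pesticides = {p.pesticide for p in config.toxicity_profiles}
    for app in config.applications:
        if app.pesticide not in pesticides:
            problems.append(
                f"application of {app.pesticide!r} without a toxicity profile")
    for nest in config.nests:
        if config.applications and nest.species not in config.intake:
            problems.append(f"no intake parameters for species {nest.species!r}")
        spec = config.diets.get(nest.nest_id)
        if spec is not None and spec.mode == "worst_case":
            if spec.field_id is not None and spec.field_id not in field_ids:
                problems.append(
                    f"nest {nest.nest_id}: worst-case diet field "
                    f"{spec.field_id!r} not in landscape")
    return problems


def _require_valid(config: ScenarioConfig) -> None:
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("invalid scenario:\n  - " + "\n  - ".join(problems))


def resolve_diet(config: ScenarioConfig, nest: NestConfig) -> DietFractionTable:
    """Materialize a nest's diet fraction table from its DietSpec."""
    spec = config.diets.get(nest.nest_id, DietSpec())
    if spec.mode == "worst_case":
        fid = spec.field_id
        if fid is None and config.landscape.fields:
            fid = config.landscape.fields[0].field_id
        if fid is None:  # no landscape at all: background-only diet
            return DietFractionTable((DietEntry(BACKGROUND,
                                                spec.food_item or "vegetation",
                                                1.0),))
        item = spec.food_item or (config.landscape.field(fid).crop_on(0)
                                  or "vegetation")
        return DietFractionTable((DietEntry(zone_id(fid, "core"), item, 1.0),))
    # landscape mode
    area = FeedingArea(nest.nest_id, nest.location, nest.feeding_radius)
    fractions = feeding_zone_overlap(area, config.landscape, spec.resolution)
    if not spec.food_weights:
        raise ConfigurationError(
            f"nest {nest.nest_id}: landscape diet mode needs food_weights")
    weights: dict[tuple[str, str], float] = {}
    for zid in fractions:
        _, kind = split_zone_id(zid)
        for (wkind, item), w in spec.food_weights.items():
            if wkind == kind:
                weights[(zid, item)] = w
    return diet_fractions(fractions, weights)


@dataclass
class _PreparedNest:
    nest: NestConfig
    diet: DietFractionTable
    series: dict[str, ExposureSeries]          # pesticide -> daily ETE
    group_multipliers: tuple[float, ...] | None


def prepare_exposure(config: ScenarioConfig) -> dict[str, _PreparedNest]:
    """Precompute the (deterministic) per-nest exposure series."""
    _require_valid(config)
    rud = {(p.pesticide, p.food_item): p for p in config.residue_params}
    apps_by_field: dict[str, list[ApplicationEvent]] = {}
    for app in config.applications:
        apps_by_field.setdefault(app.field_id, []).append(app)
    pesticides = sorted({p.pesticide for p in config.toxicity_profiles})

    prepared: dict[str, _PreparedNest] = {}
    for nest in config.nests:
        diet = resolve_diet(config, nest)
        intake = config.intake.get(nest.species)
        series: dict[str, ExposureSeries] = {}
        for pest in pesticides:
            ete = np.zeros(config.horizon_days)
            if intake is not None:
                for entry in diet.entries:
                    fid, kind = split_zone_id(entry.zone_id)
                    if fid is None:
                        continue  # background receives no deposition
                    params = rud.get((pest, entry.food_item))
                    if params is None:
                        continue
                    apps = apps_by_field.get(fid, [])
                    ete += entry.fraction * residue_series(
                        config.horizon_days, apps, params, kind)
                ete *= intake.fir_over_bw
            series[pest] = ExposureSeries(nest.nest_id, pest, ete)
        mult = intake.group_multipliers if intake is not None else None
        prepared[nest.nest_id] = _PreparedNest(nest, diet, series, mult)
    return prepared


def _nest_rng(base_seed: int, iteration: int, nest_id: str) -> np.random.Generator:
    # stable, platform-independent substream per (iteration, nest)
    return np.random.default_rng(
        [int(base_seed) + int(iteration), zlib.crc32(nest_id.encode())])


@dataclass
class SimulationResult:
    """One iteration: per-day abundance plus the rate/exposure audit trail."""

    config_name: str
    iteration: int
    nest_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    abundance: np.ndarray            # (n_days, n_nests, n_groups), end-of-day
    monthly_rates: pd.DataFrame      # nest, month, group, mortality, reproduction
    exposure: pd.DataFrame           # nest, pesticide, day, ete

    @property
    def totals(self) -> np.ndarray:  # (n_days, n_nests)
        return self.abundance.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        n_days, n_nests, n_groups = self.abundance.shape
        rows = []
        for j, nid in enumerate(self.nest_ids):
            df = pd.DataFrame(
                self.abundance[:, j, :],
                columns=[f"group_{g}" for g in range(n_groups)])
            df.insert(0, "day", np.arange(n_days))
            df.insert(0, "nest_id", nid)
            df["total"] = self.abundance[:, j, :].sum(axis=1)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def run(config: ScenarioConfig, iteration_index: int = 0,
        prepared: Mapping[str, _PreparedNest] | None = None) -> SimulationResult:
    """Run one stochastic iteration; deterministic given (config, iteration)."""
    if prepared is None:
        prepared = prepare_exposure(config)
    dpm = config.days_per_month
    n_nests = len(config.nests)
    n_groups = max(n.n_groups for n in config.nests)
    abundance = np.zeros((config.horizon_days, n_nests, n_groups), dtype=np.int64)
    rate_rows: list[dict] = []
    expo_rows: list[pd.DataFrame] = []

    for j, nest in enumerate(config.nests):
        prep = prepared[nest.nest_id]
        rng = _nest_rng(config.base_seed, iteration_index, nest.nest_id)
        state = initialize_nest(nest, rng)
        bg_mort = np.array([g.background_monthly_mortality for g in nest.age_groups])
        bg_repro = np.array([g.background_monthly_reproduction
                             for g in nest.age_groups])
        mult = (np.ones(nest.n_groups) if prep.group_multipliers is None
                else np.asarray(prep.group_multipliers))
        acute_profiles = [p for p in config.toxicity_profiles
                          if p.acute is not None]
        daily_mort = np.zeros(nest.n_groups)
        eff_repro = bg_repro.copy()

        for day in range(config.horizon_days):
            block = day // dpm
            if day % dpm == 0:
                eff_mort, eff_repro = effective_rates_for_month(
                    block, config.toxicity_profiles, prep.series,
                    bg_mort, bg_repro, dpm,
                    None if prep.group_multipliers is None
                    else prep.group_multipliers)
                daily_mort = np.array(
                    [monthly_to_daily_mortality(m, dpm) for m in eff_mort])
                for g in range(nest.n_groups):
                    rate_rows.append(dict(
                        nest_id=nest.nest_id, iteration=iteration_index,
                        month=block, group=g,
                        effective_monthly_mortality=eff_mort[g],
                        effective_monthly_reproduction=eff_repro[g]))
            # acute mortality from today's exposure
            if acute_profiles:
                acute = np.array([
                    combine_mortality(0.0, [
                        p.acute(prep.series[p.pesticide].daily_ete[day] * mult[g])
                        for p in acute_profiles])
                    for g in range(nest.n_groups)])
                if np.any(acute > 0):
                    daily_mortality_step(state, acute, rng)
            # background + chronic daily mortality
            daily_mortality_step(state, daily_mort, rng)
            # reproduction
            in_season = config.calendar_month(block) in nest.reproductive_season
            daily_reproduction_step(state, eff_repro, in_season, dpm,
                                    nest.sex_ratio_male, rng)
            advance_age(state)
            abundance[day, j, :nest.n_groups] = state.counts_by_group()

        for pest, s in prep.series.items():
            expo_rows.append(pd.DataFrame(dict(
                nest_id=nest.nest_id, pesticide=pest,
                day=np.arange(config.horizon_days), ete=s.daily_ete)))

    monthly = pd.DataFrame(rate_rows)
    exposure = (pd.concat(expo_rows, ignore_index=True) if expo_rows
                else pd.DataFrame(columns=["nest_id", "pesticide", "day", "ete"]))
    labels = tuple(g.label for g in config.nests[0].age_groups)
    return SimulationResult(config.name, iteration_index,
                            tuple(n.nest_id for n in config.nests),
                            labels, abundance, monthly, exposure)


@dataclass
class ReplicationSummary:
    """Across-iteration summary of per-nest total abundance."""

    config_name: str
    nest_ids: tuple[str, ...]
    iterations: int
    summary_mode: str
    totals: np.ndarray   # (n_iterations, n_days, n_nests)
    mean: np.ndarray     # (n_days, n_nests)
    low: np.ndarray
    high: np.ndarray

    def pooled_mean(self) -> np.ndarray:
        """Replicate-mean total abundance pooled across nests, per day."""
        return self.mean.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n_days = self.mean.shape[0]
        rows = []
        for j, nid in enumerate(self.nest_ids):
            rows.append(pd.DataFrame(dict(
                nest_id=nid, day=np.arange(n_days), mean=self.mean[:, j],
                low=self.low[:, j], high=self.high[:, j])))
        return pd.concat(rows, ignore_index=True)


def replicate(config: ScenarioConfig) -> ReplicationSummary:
    """Run ``config.iterations`` seeded iterations and summarize abundance.

    The 95% confidence band uses the normal approximation
    mean +/- 1.96 sd/sqrt(n); ``min_max`` mode reports the envelope instead.
    """
    _require_valid(config)
    prepared = prepare_exposure(config)
    totals = np.empty((config.iterations, config.horizon_days, len(config.nests)))
    for i in range(config.iterations):
        totals[i] = run(config, i, prepared).totals
    mean = totals.mean(axis=0)
    if config.summary_mode == "min_max":
        low, high = totals.min(axis=0), totals.max(axis=0)
    else:
        sd = totals.std(axis=0, ddof=1)
        half = 1.96 * sd / np.sqrt(config.iterations)
        low, high = mean - half, mean + half
    return ReplicationSummary(config.name, tuple(n.nest_id for n in config.nests),
                              config.iterations, config.summary_mode,
                              totals, mean, low, high)


def export(obj: SimulationResult | ReplicationSummary, path,
           config: ScenarioConfig | None = None) -> dict[str, Path]:
    """Write CSV tables plus a run-metadata JSON; returns the file map."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    meta: dict = {"name": obj.config_name}
    if isinstance(obj, SimulationResult):
        written["abundance"] = out / "abundance.csv"
        obj.to_frame().to_csv(written["abundance"], index=False)
        written["rates"] = out / "monthly_rates.csv"
        obj.monthly_rates.to_csv(written["rates"], index=False)
        written["exposure"] = out / "exposure.csv"
        obj.exposure.to_csv(written["exposure"], index=False)
        meta["iteration"] = obj.iteration
    else:
        written["summary"] = out / "abundance_summary.csv"
        obj.to_frame().to_csv(written["summary"], index=False)
        meta["iterations"] = obj.iterations
        meta["summary_mode"] = obj.summary_mode
    if config is not None:
        meta.update(base_seed=config.base_seed, iterations=config.iterations,
                    horizon_days=config.horizon_days,
                    days_per_month=config.days_per_month,
                    start_month=config.start_month,
                    summary_mode=config.summary_mode,
                    nests=[n.nest_id for n in config.nests])
    written["metadata"] = out / "metadata.json"
    written["metadata"].write_text(json.dumps(meta, indent=2))
    return written
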