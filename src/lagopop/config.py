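"""Scenario file reading and writing (YAML).

The scenario file is a hierarchical document with sections ``run``,
``species``, ``nests``, ``landscape``, ``applications``, ``residues`` and
``toxicity``.  Toxicity may be given either as raw endpoints (LD0/LD50,
NOAEL/LOAEL plus interspecies factors — the dose-response lines are derived
at load time) or as pre-derived slope/intercept pairs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from shapely.geometry import Polygon, box

from .demography import AgeGroupSpec, NestConfig, MONTH_NAMES
from .effects import (EndpointInputs, LinearDoseResponse,
                      PesticideToxicityProfile, derive_acute_dr,
                      derive_chronic_dr)
from .engine import DietSpec, ScenarioConfig
from .errors import ConfigurationError
from .exposure import ApplicationEvent, IntakeParameters, ResidueParameters
from .landscape import CropInterval, Field, Landscape

__all__ = ["load_scenario", "dump_scenario", "scenario_from_dict",
           "scenario_to_dict"]


def _age_groups_from(spec: list[dict]) -> tuple[AgeGroupSpec, ...]:
    groups = []
    for i, g in enumerate(spec):
        groups.append(AgeGroupSpec(
            index=i, label=str(g.get("label", f"group_{i}")),
            min_age_days=int(g["min_age_days"]),
            background_monthly_mortality=float(g["monthly_mortality"]),
            background_monthly_reproduction=float(
                g.get("monthly_reproduction", 0.0))))
    return tuple(groups)


def _dr_from(node: dict, kind: str) -> tuple[LinearDoseResponse, int]:
    """Build a dose-response line from either raw endpoints or coefficients."""
    window = int(node.get("twa_window", 1))
    if "slope" in node:
        return (LinearDoseResponse(float(node["slope"]),
                                   float(node.get("intercept", 0.0))), window)
    if kind == "acute":
        inputs = EndpointInputs(
            ld0=node.get("ld0"), ld50=node.get("ld50"),
            interspecies_factor_acute_ld0=float(node.get("factor_ld0", 1.0)),
            interspecies_factor_acute_ld50=float(node.get("factor_ld50", 1.0)))
        return derive_acute_dr(inputs), window
    inputs = EndpointInputs(
        noael=node.get("noael"), loael=node.get("loael"),
        interspecies_factor_chronic=float(node.get("factor", 1.0)),
        loael_effect=float(node.get("loael_effect", 0.25)))
    return derive_chronic_dr(inputs).dose_response, window


def _profile_from(node: dict) -> PesticideToxicityProfile:
    acute = chronic = repro = None
    cw = rw = 1
    if "acute" in node:
        acute, _ = _dr_from(node["acute"], "acute")
    if "chronic" in node:
        chronic, cw = _dr_from(node["chronic"], "chronic")
    if "reproduction" in node:
        repro, rw = _dr_from(node["reproduction"], "reproduction")
    return PesticideToxicityProfile(
        pesticide=str(node["pesticide"]), acute=acute,
        chronic=chronic, chronic_twa_window_days=cw,
        reproduction=repro, reproduction_twa_window_days=rw,
        mortality_lag_months=int(node.get("mortality_lag_months", 1)),
        reproduction_lag_months=tuple(
            node.get("reproduction_lag_months", (1, 2))))


def _field_from(node: dict) -> Field:
    if "rectangle" in node:
        x0, y0, x1, y1 = (float(v) for v in node["rectangle"])
        poly = box(x0, y0, x1, y1)
    elif "polygon" in node:
        poly = Polygon([(float(x), float(y)) for x, y in node["polygon"]])
    else:
        raise ConfigurationError("field needs a 'rectangle' or 'polygon'")
    if "crop" in node and "crop_schedule" not in node:
        schedule = (CropInterval(str(node["crop"]), 0, 10 ** 9),)
    else:
        schedule = tuple(CropInterval(str(c["crop"]), int(c["start_day"]),
                                      int(c["end_day"]))
                         for c in node.get("crop_schedule", []))
    return Field(field_id=str(node["field_id"]), polygon=poly,
                 crop_schedule=schedule,
                 inner_band_width=float(node.get("inner_band_width", 0.0)),
                 outer_band_width=float(node.get("outer_band_width", 0.0)))


def _diet_from(node: dict | None) -> DietSpec:
    if not node:
        return DietSpec()
    mode = node.get("mode", "worst_case")
    if mode == "worst_case":
        return DietSpec(mode="worst_case", field_id=node.get("field_id"),
                        food_item=node.get("food_item"))
    weights = {(str(w["zone"]), str(w["item"])): float(w["weight"])
               for w in node.get("food_weights", [])}
    return DietSpec(mode="landscape", food_weights=weights,
                    resolution=node.get("resolution"))


def scenario_from_dict(doc: dict[str, Any]) -> ScenarioConfig:
    run = doc.get("run", {})
    species = doc.get("species", {})
    nests = []
    diets = {}
    for n in doc.get("nests", []):
        sp_name = str(n["species"])
        if sp_name not in species:
            raise ConfigurationError(f"nest references unknown species {sp_name!r}")
        sp = species[sp_name]
        nests.append(NestConfig(
            nest_id=str(n["nest_id"]),
            location=tuple(float(v) for v in n.get("location", (0.0, 0.0))),
            species=sp_name,
            age_groups=_age_groups_from(sp["age_groups"]),
            initial_counts=tuple(int(c) for c in n["initial_counts"]),
            sex_ratio_male=float(sp.get("sex_ratio_male", 0.5)),
            reproductive_season=frozenset(sp.get("reproductive_season", ())),
            feeding_radius=float(n.get("feeding_radius", 250.0))))
        diets[str(n["nest_id"])] = _diet_from(n.get("diet"))
    intake = {}
    for sp_name, sp in species.items():
        if "fir_over_bw" in sp:
            gm = sp.get("group_multipliers")
            intake[sp_name] = IntakeParameters(
                sp_name, float(sp["fir_over_bw"]),
                tuple(gm) if gm else None)
    landscape = Landscape(fields=tuple(
        _field_from(f) for f in doc.get("landscape", {}).get("fields", [])))
    applications = tuple(ApplicationEvent(
        pesticide=str(a["pesticide"]), field_id=str(a["field_id"]),
        day=int(a["day"]), rate=float(a["rate"]),
        drift_fractions=dict(a.get("drift", {})))
        for a in doc.get("applications", []))
    residues = tuple(ResidueParameters(
        str(r["pesticide"]), str(r["food_item"]),
        float(r["rud"]), float(r["dt50"]))
        for r in doc.get("residues", []))
    profiles = tuple(_profile_from(t) for t in doc.get("toxicity", []))
    return ScenarioConfig(
        name=str(doc.get("name", "scenario")),
        horizon_days=int(run["horizon_days"]),
        nests=tuple(nests), landscape=landscape,
        applications=applications, residue_params=residues,
        intake=intake, toxicity_profiles=profiles, diets=diets,
        days_per_month=int(run.get("days_per_month", 30)),
        start_month=run.get("start_month", "december"),
        iterations=int(run.get("iterations", 50)),
        base_seed=int(run.get("base_seed", 0)),
        summary_mode=run.get("summary_mode", "mean_ci95"))


def scenario_to_dict(config: ScenarioConfig) -> dict[str, Any]:
    species: dict[str, Any] = {}
    nests = []
    for nest in config.nests:
        if nest.species not in species:
            sp: dict[str, Any] = {
                "age_groups": [
                    {"label": g.label, "min_age_days": g.min_age_days,
                     "monthly_mortality": g.background_monthly_mortality,
                     "monthly_reproduction": g.background_monthly_reproduction}
                    for g in nest.age_groups],
                "sex_ratio_male": nest.sex_ratio_male,
                "reproductive_season": sorted(
                    MONTH_NAMES[m] for m in nest.reproductive_season),
            }
            ip = config.intake.get(nest.species)
            if ip is not None:
                sp["fir_over_bw"] = ip.fir_over_bw
                if ip.group_multipliers:
                    sp["group_multipliers"] = list(ip.group_multipliers)
            species[nest.species] = sp
        node: dict[str, Any] = {
            "nest_id": nest.nest_id, "species": nest.species,
            "location": list(nest.location),
            "feeding_radius": nest.feeding_radius,
            "initial_counts": list(nest.initial_counts)}
        diet = config.diets.get(nest.nest_id)
        if diet is not None:
            if diet.mode == "worst_case":
                node["diet"] = {"mode": "worst_case",
                                "field_id": diet.field_id,
                                "food_item": diet.food_item}
            else:
                node["diet"] = {
                    "mode": "landscape", "resolution": diet.resolution,
                    "food_weights": [
                        {"zone": z, "item": i, "weight": w}
                        for (z, i), w in (diet.food_weights or {}).items()]}
        nests.append(node)
    fields = []
    for f in config.landscape.fields:
        fields.append({
            "field_id": f.field_id,
            "polygon": [list(xy) for xy in f.polygon.exterior.coords],
            "inner_band_width": f.inner_band_width,
            "outer_band_width": f.outer_band_width,
            "crop_schedule": [
                {"crop": c.crop, "start_day": c.start_day, "end_day": c.end_day}
                for c in f.crop_schedule]})
    toxicity = []
    for p in config.toxicity_profiles:
        node = {"pesticide": p.pesticide,
                "mortality_lag_months": p.mortality_lag_months,
                "reproduction_lag_months": list(p.reproduction_lag_months)}
        if p.acute:
            node["acute"] = {"slope": p.acute.slope,
                             "intercept": p.acute.intercept}
        if p.chronic:
            node["chronic"] = {"slope": p.chronic.slope,
                               "intercept": p.chronic.intercept,
                               "twa_window": p.chronic_twa_window_days}
        if p.reproduction:
            node["reproduction"] = {"slope": p.reproduction.slope,
                                    "intercept": p.reproduction.intercept,
                                    "twa_window": p.reproduction_twa_window_days}
        toxicity.append(node)
    return {
        "name": config.name,
        "run": {"horizon_days": config.horizon_days,
                "days_per_month": config.days_per_month,
                "start_month": MONTH_NAMES[config.start_month],
                "iterations": config.iterations,
                "base_seed": config.base_seed,
                "summary_mode": config.summary_mode},
        "species": species,
        "nests": nests,
        "landscape": {"fields": fields},
        "applications": [
            {"pesticide": a.pesticide, "field_id": a.field_id, "day": a.day,
             "rate": a.rate, "drift": dict(a.drift_fractions)}
            for a in config.applications],
        "residues": [
            {"pesticide": r.pesticide, "food_item": r.food_item,
             "rud": r.rud, "dt50": r.dt50}
            for r in config.residue_params],
        "toxicity": toxicity,
    }


def load_scenario(path) -> ScenarioConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: not a mapping document")
    return scenario_from_dict(doc)


def dump_scenario(config: ScenarioConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(config), sort_keys=False))
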