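"""Shared YAML/JSON configuration for priors, thresholds, posterior settings
and simulation scenarios.

Schema (all sections optional; omitted keys fall back to the trial's
prespecified defaults)::

    prior:
      control: {mean: 0.0, scale: 0.3, convention: precision}
      effect:  {mean: 0.0, or_ci_upper: 30, level: 0.95}
    posterior: {n_draws: 10000, seed: 0}
    stopping:  {E: 0.95, F: 0.95, D: 0.01}
    scenario:  {p_control: 0.3, delta: 0.01, cohort_size: 300,
                outcome_lag_weeks: 2, max_weeks: 50, enrolment_cap: 15000}
    scenarios: [ {p_control: ..., delta: ...}, ... ]
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .decisions import DecisionThresholds
from .priors import PriorSpec, logor_sd_from_ci
from .simulate import ScenarioSpec

__all__ = ["Config", "load_config", "prior_from_dict", "thresholds_from_dict", "scenario_from_dict"]


class ConfigError(ValueError):
    """Malformed or unreadable configuration."""


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def prior_from_dict(d: dict | None) -> PriorSpec:
    d = d or {}
    control = d.get("control", {})
    effect = d.get("effect", {})
    kwargs: dict = {}
    if "mean" in control:
        kwargs["control_logit_mean"] = float(control["mean"])
    if "scale" in control:
        kwargs["control_logit_scale"] = float(control["scale"])
    if "convention" in control:
        kwargs["control_scale_convention"] = str(control["convention"])
    if "mean" in effect:
        kwargs["effect_logor_mean"] = float(effect["mean"])
    if "sd" in effect:
        kwargs["effect_logor_sd"] = float(effect["sd"])
    elif "or_ci_upper" in effect:
        kwargs["effect_logor_sd"] = logor_sd_from_ci(
            float(effect["or_ci_upper"]), float(effect.get("level", 0.95))
        )
    return PriorSpec(**kwargs)


def thresholds_from_dict(d: dict | None) -> DecisionThresholds:
    d = d or {}
    return DecisionThresholds(
        efficacy_E=float(d.get("E", 0.95)),
        futility_F=float(d.get("F", 0.95)),
        negligible_D=float(d.get("D", 0.01)),
    )


def scenario_from_dict(d: dict) -> ScenarioSpec:
    try:
        return ScenarioSpec(
            p_control=float(d["p_control"]),
            delta=float(d["delta"]),
            cohort_size=int(d.get("cohort_size", 300)),
            outcome_lag_weeks=int(d.get("outcome_lag_weeks", 2)),
            max_weeks=int(d.get("max_weeks", 50)),
            enrolment_cap=int(d.get("enrolment_cap", 15_000)),
            accrual=d.get("accrual", "fixed"),
            randomization=d.get("randomization", "exact"),
        )
    except KeyError as exc:
        raise ConfigError(f"scenario is missing required key {exc}") from exc


@dataclass(frozen=True)
class Config:
    prior: PriorSpec
    thresholds: DecisionThresholds
    n_draws: int
    seed: int
    scenario: ScenarioSpec | None
    scenarios: tuple[ScenarioSpec, ...]


def load_config(path: str | Path | None) -> Config:
    """Load a YAML or JSON config file; ``None`` yields all defaults."""
    raw = _load_mapping(path) if path is not None else {}
    posterior = raw.get("posterior", {})
    scenario = scenario_from_dict(raw["scenario"]) if "scenario" in raw else None
    scenarios = tuple(scenario_from_dict(s) for s in raw.get("scenarios", []))
    return Config(
        prior=prior_from_dict(raw.get("prior")),
        thresholds=thresholds_from_dict(raw.get("stopping")),
        n_draws=int(posterior.get("n_draws", 10_000)),
        seed=int(posterior.get("seed", 0)),
        scenario=scenario,
        scenarios=scenarios,
    )
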