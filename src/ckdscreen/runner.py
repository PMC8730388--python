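"""End-to-end orchestration of scenario runs.

One initial population is built from the master seed and cloned into
every scenario arm; arms advance independently but share per-individual
random streams (common random numbers), so they diverge only where the
scenarios' decisions differ.  Individuals are followed in annual cycles
until death or censoring at the age cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import outcomes, population, progression
from ._rng import CRNStream
from .params import (
    ParameterSet,
    ScenarioSpec,
    generate_fixture_parameters,
    load_parameters,
)

__all__ = ["RunConfig", "default_scenarios", "load_run_config", "run_simulation"]

AGE_MIN = 18


def default_scenarios() -> list[ScenarioSpec]:
    """Base case plus the three standard testing scenarios."""
    return [
        ScenarioSpec("base", "none"),
        ScenarioSpec("diabetes", "diabetes"),
        ScenarioSpec("diabetes-or-hypertension", "diabetes-or-hypertension"),
        ScenarioSpec("all", "all"),
    ]


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    n_individuals: int = 100_000
    seed: int = 1
    scenarios: list[ScenarioSpec] = dc_field(default_factory=default_scenarios)
    params_path: str | None = None  # None -> built-in fixture parameter set
    out_dir: str | None = None
    profile_cohort_size: int = 1_000_000

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")


def load_run_config(path) -> RunConfig:
    """Read a YAML run configuration (keys mirror :class:`RunConfig`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenarios = [
        ScenarioSpec(
            name=s["name"],
            eligibility=s["eligibility"],
            testing_interval_years=int(s.get("testing_interval_years", 2)),
            exclude_if_on_raas_blocker=bool(s.get("exclude_if_on_raas_blocker", True)),
        )
        for s in raw.get("scenarios", [])
    ] or default_scenarios()
    return RunConfig(
        n_individuals=int(raw.get("n_individuals", 100_000)),
        seed=int(raw.get("seed", 1)),
        scenarios=scenarios,
        params_path=raw.get("params_path"),
        out_dir=raw.get("out_dir"),
        profile_cohort_size=int(raw.get("profile_cohort_size", 1_000_000)),
    )


def _run_arm(initial, p, scenario, rng, stats=None):
    state = initial.clone()
    max_cycles = int(p.age_cap) - AGE_MIN
    for _ in range(max_cycles):
        if not state.active.any():
            break
        progression.advance_year(state, p, scenario, rng, stats=stats)
    return state


def run_simulation(
    config: RunConfig,
    params: ParameterSet | None = None,
    profile: population.RenalAgeProfile | None = None,
    keep_states: bool = False,
) -> dict:
    """Run every scenario arm on a common initial population.

    Returns a dict with per-scenario summaries, incremental comparisons
    against the base case, run statistics of the base arm, and (with
    ``keep_states``) the final state matrices.  If ``config.out_dir`` is
    set, summary/incremental CSV tables and JSON metadata are written.
    """
    if params is None:
        params = (
            load_parameters(config.params_path)
            if config.params_path
            else generate_fixture_parameters(config.seed)
        )
    rng = CRNStream(config.seed)
    if profile is None:
        profile = population.derive_renal_age_profiles(params, config.profile_cohort_size, rng)
    initial = population.build_initial_population(config.n_individuals, params, profile, rng)

    summaries, states, base_stats = {}, {}, {}
    for scenario in config.scenarios:
        stats = base_stats if scenario.eligibility == "none" else None
        final = _run_arm(initial, params, scenario, rng, stats=stats)
        summaries[scenario.name] = outcomes.summarize_scenario(final, params, name=scenario.name)
        if keep_states:
            states[scenario.name] = final

    base_name = next((s.name for s in config.scenarios if s.eligibility == "none"), None)
    incremental = {}
    if base_name is not None:
        for scenario in config.scenarios:
            if scenario.name != base_name:
                incremental[scenario.name] = outcomes.compare_scenarios(
                    summaries[base_name], summaries[scenario.name]
                )

    results = {
        "summaries": summaries,
        "incremental": incremental,
        "base_stats": base_stats,
        "config": config,
        "initial_state": initial if keep_states else None,
        "states": states if keep_states else None,
    }
    if config.out_dir:
        _write_outputs(results, params, config)
    return results


def _summary_frame(summaries: dict) -> pd.DataFrame:
    rows = []
    for name, s in summaries.items():
        for metric, val in s.items():
            if isinstance(val, dict) and "mean" in val:
                rows.append(
                    {"scenario": name, "metric": metric, "mean": val["mean"],
                     "ci_low": val["ci"][0], "ci_high": val["ci"][1]}
                )
    return pd.DataFrame(rows)


def _incremental_frame(incremental: dict) -> pd.DataFrame:
    rows = []
    for name, comp in incremental.items():
        for disc in ("undisc", "disc"):
            for k, v in comp[disc].items():
                if k != "note":
                    rows.append({"scenario": name, "discounting": disc, "metric": k, "value": v})
    return pd.DataFrame(rows)


def _write_outputs(results: dict, params: ParameterSet, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _summary_frame(results["summaries"]).to_csv(out / "summary.csv", index=False)
    if results["incremental"]:
        _incremental_frame(results["incremental"]).to_csv(out / "incremental.csv", index=False)
    meta = {
        "n_individuals": config.n_individuals,
        "seed": config.seed,
        "profile_cohort_size": config.profile_cohort_size,
        "scenarios": [s.name for s in config.scenarios],
        "parameter_source": config.params_path or "built-in fixture",
        "base_stats": results["base_stats"],
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
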