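"""End-to-end pipeline: trials -> summaries -> EZ parameters -> fit check ->
group-level effects, with every stage communicating through documented CSV
schemas so stages can be re-run individually from intermediates."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datatypes import StudyDesign, TaskSpec
from .defaults import DEFAULT_TASKS
from .ez_cdm import estimate_circular_params
from .ez_dm import estimate_choice_params
from .fit_assessment import posterior_predictive_check
from .inference import McmcConfig, OUTCOMES
from .io import (combined_trials, config_hash, read_trials, split_families,
                 write_trials_csv)
from .models import RetroCueEffectsModel
from .preprocess import summarize_trials, trim_rts
from .simulate import cohort_to_csv_frame, generate_cohort


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    s: float = 1.0
    dt: float = 0.001
    trials_path: str | None = None          # read trials instead of simulating
    column_map: dict | str | None = None
    simulate: dict = field(default_factory=dict)   # n_younger, n_older, tasks
    mcmc: dict = field(default_factory=dict)
    outcomes: tuple = OUTCOMES
    pooled_fit_check: bool = True
    on_nonconvergence: str = "raise"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def design_from_config(sim: dict, seed: int) -> StudyDesign:
    tasks = tuple(
        TaskSpec(t["name"], n_trials=int(t.get("n_trials", 80)),
                 cue_proportion=float(t.get("cue_proportion", 0.5)),
                 load=t.get("load", {}))
        for t in sim["tasks"]) if "tasks" in sim else DEFAULT_TASKS
    return StudyDesign(
        tasks=tasks,
        n_participants={"younger": int(sim.get("n_younger", 20)),
                        "older": int(sim.get("n_older", 20))},
        seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns {artifact name: path or frame}.

    Stage failures after partial progress leave the already-written artifacts
    in place. Deterministic under (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"package_version": __version__,
                 "config_hash": config_hash(config.__dict__ | {"column_map": str(config.column_map)}),
                 "seed": config.seed, "stages": {}}
    artifacts: dict = {"log": out / "pipeline_log.json"}

    def _save_log():
        with open(artifacts["log"], "w") as fh:
            json.dump(log, fh, indent=2, default=str)

    # 1 — trials
    if config.trials_path:
        trials = read_trials(config.trials_path, config.column_map)
        choice, circular = split_families(trials)
        log["stages"]["load"] = {"n_rows": len(trials)}
    else:
        design = design_from_config(config.simulate, config.seed)
        cohort = generate_cohort(design, seed=config.seed, dt=config.dt)
        choice, circular = cohort["choice"], cohort["circular"]
        trials_csv = out / "trials.csv"
        write_trials_csv(cohort_to_csv_frame(cohort), trials_csv)
        artifacts["trials"] = trials_csv
        log["stages"]["simulate"] = {
            "n_choice": len(choice), "n_circular": len(circular),
            "diagnostics": cohort["diagnostics"]}

    # 2 — trim + summaries
    trimmed_parts, reports = [], []
    for fam, frame in (("cd", choice), ("de", circular)):
        if frame.empty:
            continue
        t, rep = trim_rts(frame, fam)
        trimmed_parts.append(t)
        reports.append(rep)
    trimmed = combined_trials(*trimmed_parts) if len(trimmed_parts) == 2 else trimmed_parts[0]
    trim_report = pd.concat(reports, ignore_index=True)
    summaries, _ = summarize_trials(trimmed, trim=False)
    summaries.to_csv(out / "summaries.csv", index=False)
    trim_report.to_csv(out / "trim_report.csv", index=False)
    artifacts |= {"summaries": out / "summaries.csv",
                  "trim_report": out / "trim_report.csv"}
    log["stages"]["preprocess"] = {
        "n_cells": len(summaries),
        "n_removed": int(trim_report["n_input"].sum() - trim_report["n_kept"].sum())}
    _save_log()

    # 3 — EZ estimation
    parts = []
    cd_sum = summaries[summaries["family"] == "cd"]
    de_sum = summaries[summaries["family"] == "de"]
    if not cd_sum.empty:
        parts.append(estimate_choice_params(cd_sum, s=config.s))
    if not de_sum.empty:
        parts.append(estimate_circular_params(de_sum, s=config.s))
    params = pd.concat(parts, ignore_index=True)
    params.to_csv(out / "params.csv", index=False)
    artifacts["params"] = out / "params.csv"
    n_err = int(params["status"].str.startswith("error").sum())
    log["stages"]["fit_ez"] = {"n_cells": len(params), "n_errors": n_err}
    _save_log()

    # 4 — fit check
    fit_report = posterior_predictive_check(
        params, trimmed, seed=config.seed + 1, pooled=config.pooled_fit_check,
        dt=config.dt)
    fit_report.to_csv(out / "fit_report.csv", index=False)
    artifacts["fit_report"] = out / "fit_report.csv"
    log["stages"]["check_fit"] = {"min_r": float(fit_report["r"].min())}
    _save_log()

    # 5 — group-level effects
    cfg = McmcConfig(**({"seed": config.seed + 2} | config.mcmc))
    effect_tables, overall_tables, age_tables, summaries_txt = [], [], [], []
    for outcome in config.outcomes:
        res = RetroCueEffectsModel(params, outcome).fit(
            cfg, on_nonconvergence=config.on_nonconvergence)
        effect_tables.append(res.effect_table())
        overall_tables.append(res.overall_table())
        age_tables.append(res.age_table())
        summaries_txt.append(res.summary())
    pd.concat(effect_tables, ignore_index=True).to_csv(out / "effects.csv", index=False)
    pd.concat(overall_tables, ignore_index=True).to_csv(out / "contrasts.csv", index=False)
    pd.concat(age_tables, ignore_index=True).to_csv(out / "age_effects.csv", index=False)
    (out / "effects_summary.txt").write_text("\n\n".join(summaries_txt) + "\n")
    artifacts |= {"effects": out / "effects.csv", "contrasts": out / "contrasts.csv",
                  "age_effects": out / "age_effects.csv",
                  "effects_summary": out / "effects_summary.txt"}
    log["stages"]["infer"] = {"outcomes": list(config.outcomes),
                              "mcmc": cfg.__dict__}
    _save_log()
    return artifacts
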