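"""CSV/YAML I/O and schema handling for the pipeline.

On disk, trial tables are a single CSV with header
``participant, age_group, task, condition, load, correct, rt, response_deg,
target_deg``: angle columns are empty for change-detection rows, correctness
is empty for delayed-estimation rows, and angles are degrees in [0, 360).
Internally angles are radians in [-pi, pi). A column-mapping config adapts
externally deposited files (different column names, value labels or RT units)
without code changes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import task_family, wrap_angle

TRIAL_COLUMNS = ["participant", "age_group", "task", "condition", "load",
                 "correct", "rt", "response_deg", "target_deg"]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def load_column_map(path_or_dict):
    if path_or_dict is None:
        return {}
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            return yaml.safe_load(fh) or {}
    return dict(path_or_dict)


def read_trials(path, column_map=None) -> pd.DataFrame:
    """Read a trial CSV into the internal representation.

    column_map keys: ``columns`` ({canonical: source name}), ``task_values``
    and ``condition_values`` (source label -> canonical label), ``rt_scale``
    (multiplier to seconds, e.g. 0.001 for milliseconds).
    """
    cmap = load_column_map(column_map)
    df = pd.read_csv(path)
    renames = {src: dst for dst, src in cmap.get("columns", {}).items()}
    df = df.rename(columns=renames)

    required = {"participant", "task", "condition", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"trial table lacks column(s) {sorted(missing)}; map source "
            "columns onto them via the column-mapping config")
    for key in ("task", "condition"):
        vals = cmap.get(f"{key}_values")
        if vals:
            df[key] = df[key].map(lambda v: vals.get(v, v))
    df["rt"] = pd.to_numeric(df["rt"], errors="coerce") * float(cmap.get("rt_scale", 1.0))
    if (df["rt"] <= 0).any() or df["rt"].isna().any():
        raise SchemaError("all RTs must be positive seconds after mapping")
    bad = ~df["task"].map(lambda t: t in _known_tasks())
    if bad.any():
        raise SchemaError(f"unknown task label(s): {sorted(df.loc[bad, 'task'].unique())}")

    fam = df["task"].map(task_family)
    if (fam == "cd").any() and "correct" not in df.columns:
        raise SchemaError("change-detection rows need a 'correct' column")
    if (fam == "de").any():
        for col in ("response_deg", "target_deg"):
            if col not in df.columns:
                raise SchemaError(f"delayed-estimation rows need a '{col}' column")
        df["response_angle"] = wrap_angle(np.radians(df["response_deg"]))
        df["target_angle"] = wrap_angle(np.radians(df["target_deg"]))
    if "correct" in df.columns:
        df["correct"] = pd.to_numeric(df["correct"], errors="coerce")
    if "age_group" not in df.columns:
        df["age_group"] = "unknown"
    return df


def _known_tasks():
    from .datatypes import TASKS

    return set(TASKS)


def split_families(trials: pd.DataFrame):
    """(choice rows with bool correct, circular rows with radian angles)."""
    fam = trials["task"].map(task_family)
    choice = trials[fam == "cd"].copy()
    if not choice.empty:
        if choice["correct"].isna().any():
            raise SchemaError("missing correctness on change-detection rows")
        choice["correct"] = choice["correct"].astype(float).astype(bool)
    circular = trials[fam == "de"].copy()
    return choice, circular


def combined_trials(choice: pd.DataFrame, circular: pd.DataFrame) -> pd.DataFrame:
    """Stack the two families into one internal table (union of columns)."""
    return pd.concat([choice, circular], ignore_index=True, sort=False)


def write_trials_csv(frame: pd.DataFrame, path):
    frame.to_csv(path, index=False, float_format="%.10g")


def read_group_means(path) -> dict:
    """Read a long-format cell-means CSV (task, age_group, condition, nu, a,
    ter) into the {(task, group): {param: (base, effect)}} layout used by the
    cohort generator."""
    df = pd.read_csv(path)
    need = {"task", "age_group", "condition", "nu", "a", "ter"}
    if not need <= set(df.columns):
        raise SchemaError(f"group-means table needs columns {sorted(need)}")
    out = {}
    key = df.set_index(["task", "age_group", "condition"])
    for (task, group), _ in df.groupby(["task", "age_group"]):
        base = key.loc[(task, group, "no_cue")]
        cue = key.loc[(task, group, "retro_cue")]
        out[(task, group)] = {p: (float(base[p]), float(cue[p]) - float(base[p]))
                              for p in ("nu", "a", "ter")}
    return out


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
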