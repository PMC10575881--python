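"""Default study conditions for the synthetic retro-cue cohort.

The synthetic cohort emulates a two-session ageing study in which younger and
older adults completed four working-memory retro-cue tasks: change detection
(CD, two-choice) and delayed estimation (DE, continuous circular report), each
with colors and with orientations as memoranda. Group-level diffusion
parameter means below are the posterior means estimated for that design
(no-cue baseline plus the signed retro-cue effect per cell); they define the
generating conditions for simulation studies and parameter-recovery checks.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import AGE_GROUPS, CONDITIONS, StudyDesign, TaskSpec

# (task, age_group) -> parameter -> (no_cue_mean, retro_cue_effect).
# Effects are signed: retro-cue cell mean = no-cue mean + effect. Retro-cues
# raise drift, lower nondecision time in every task; boundary shifts down in
# CD and up in DE.
GROUP_PARAM_MEANS = {
    ("color_cd", "younger"): {"nu": (1.25, 0.75), "ter": (0.64, -0.27), "a": (1.13, -0.04)},
    ("color_cd", "older"): {"nu": (0.86, 0.51), "ter": (0.96, -0.26), "a": (1.48, -0.13)},
    ("orientation_cd", "younger"): {"nu": (0.91, 0.66), "ter": (0.75, -0.24), "a": (1.38, -0.16)},
    ("orientation_cd", "older"): {"nu": (0.51, 0.21), "ter": (1.00, -0.22), "a": (1.67, -0.25)},
    ("color_de", "younger"): {"nu": (0.87, 0.67), "ter": (1.29, -0.93), "a": (1.92, 1.11)},
    ("color_de", "older"): {"nu": (0.62, 0.58), "ter": (1.67, -0.93), "a": (2.11, 0.54)},
    ("orientation_de", "younger"): {"nu": (1.03, 0.58), "ter": (0.91, -0.44), "a": (1.52, 0.28)},
    ("orientation_de", "older"): {"nu": (0.81, 0.40), "ter": (1.04, -0.34), "a": (1.86, 0.22)},
}

# Between-participant SDs for the truncated-normal heterogeneity around the
# cell means (evidence units / seconds).
DEFAULT_HETEROGENEITY = {"nu": 0.25, "a": 0.30, "ter": 0.15}

# Memory loads were staircase-calibrated per age group in the emulated study;
# fractional values denote trial mixtures of the two adjacent set sizes
# (fraction of ceil-load trials = fractional part, e.g. 5.4 -> 60% 5, 40% 6).
DEFAULT_TASKS = (
    TaskSpec("color_cd", n_trials=80, load={"younger": 6.0, "older": 5.0}),
    TaskSpec("orientation_cd", n_trials=80, load={"younger": 5.4, "older": 4.6}),
    TaskSpec("color_de", n_trials=100, load={"younger": 5.8, "older": 4.5}),
    TaskSpec("orientation_de", n_trials=100, load={"younger": 6.0, "older": 4.0}),
)


def default_design(n_younger: int = 172, n_older: int = 174, seed: int = 0) -> StudyDesign:
    """Study design at the emulated cohort's sample sizes (override for speed)."""
    return StudyDesign(
        tasks=DEFAULT_TASKS,
        n_participants={"younger": n_younger, "older": n_older},
        seed=seed,
    )


def group_means_frame() -> pd.DataFrame:
    """Group-level cell means as a long table (task, age_group, condition, nu, a, ter)."""
    rows = []
    for (task, group), pars in GROUP_PARAM_MEANS.items():
        for cond in CONDITIONS:
            rec = {"task": task, "age_group": group, "condition": cond}
            for p, (base, eff) in pars.items():
                rec[p] = base if cond == "no_cue" else base + eff
            rows.append(rec)
    return pd.DataFrame(rows)


def cell_mean(task: str, age_group: str, condition: str, param: str) -> float:
    base, eff = GROUP_PARAM_MEANS[(task, age_group)][param]
    return base if condition == "no_cue" else base + eff


__all__ = [
    "GROUP_PARAM_MEANS",
    "DEFAULT_HETEROGENEITY",
    "DEFAULT_TASKS",
    "default_design",
    "group_means_frame",
    "cell_mean",
    "AGE_GROUPS",
]
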