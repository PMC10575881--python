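"""Model-fit check by observed-vs-generated summary correlations.

For every participant x condition cell, synthetic trials are regenerated from
the fitted EZ parameters (matching the observed post-trim trial counts), and
participant-level summary statistics of the observed and generated data are
correlated across participants within each task x age group: proportion
correct (CD) or circular variance (DE), plus the .25/.50/.75 RT quantiles
(correct-trial RTs for CD, all RTs for DE — mirroring the estimator inputs).
High correlations mean the three-parameter model reproduces the individual
differences it was fitted to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DMParams, task_family, wrap_angle
from .simulate import DEFAULT_DT, simulate_choice_trials, simulate_circular_trials

_QS = (25, 50, 75)


def _cell_stats(family: str, correct, rt, resp=None, target=None):
    """(accuracy statistic, q25, q50, q75) for one cell."""
    rt = np.asarray(rt, dtype=float)
    if family == "cd":
        correct = np.asarray(correct, dtype=bool)
        acc = float(correct.mean())
        qrt = rt[correct]
        if qrt.size == 0:
            return None
    else:
        err = wrap_angle(np.asarray(resp, float) - np.asarray(target, float))
        acc = 1.0 - float(np.abs(np.exp(1j * err).mean()))
        qrt = rt
    q = np.percentile(qrt, _QS)
    return (acc, *q)


def posterior_predictive_check(
    params: pd.DataFrame,
    trials: pd.DataFrame,
    seed: int = 0,
    pooled: bool = True,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Correlate observed and parameter-generated summary statistics.

    Parameters
    ----------
    params : fitted EZ table (participant, age_group, task, condition,
        nu, a, ter, s, status); rows with error status are excluded and counted.
    trials : the (trimmed) trial table the parameters were fitted to.
    pooled : concatenate the two cue conditions before correlating (each
        participant contributes one point per condition); with pooled=False
        correlations are computed per condition and averaged over conditions
        via Fisher z.

    Returns a report with one row per task x age group x statistic
    (accuracy 'pc'/'cv', 'rt_q25', 'rt_q50', 'rt_q75') and columns r,
    n_participants, n_excluded_cells.
    """
    rng_root = np.random.SeedSequence(seed)
    pkey = params.set_index(["participant", "task", "condition"])

    rows = []
    for (task, group), sub in trials.groupby(["task", "age_group"], sort=False):
        family = task_family(task)
        rng = np.random.default_rng(rng_root.spawn(1)[0])
        obs_pts = {s: [] for s in range(4)}
        gen_pts = {s: [] for s in range(4)}
        cond_ids = []
        n_excluded = 0
        participants = set()
        for (pid, cond), cell in sub.groupby(["participant", "condition"], sort=False):
            try:
                prow = pkey.loc[(pid, task, cond)]
            except KeyError:
                n_excluded += 1
                continue
            status = str(prow.get("status", "ok"))
            if status.startswith("error") or not np.isfinite(prow["nu"]):
                n_excluded += 1
                continue
            pars = DMParams(float(prow["nu"]), float(prow["a"]),
                            max(float(prow["ter"]), 0.0), float(prow.get("s", 1.0)))
            n = len(cell)
            if family == "cd":
                obs = _cell_stats("cd", cell["correct"], cell["rt"])
                g_correct, g_rt, _ = simulate_choice_trials(pars, n, dt=dt, rng=rng)
                gen = _cell_stats("cd", g_correct, g_rt)
            else:
                obs = _cell_stats("de", None, cell["rt"], cell["response_angle"],
                                  cell["target_angle"])
                target = rng.uniform(-np.pi, np.pi, size=n)
                g_resp, g_rt, _ = simulate_circular_trials(pars, target, dt=dt, rng=rng)
                gen = _cell_stats("de", None, g_rt, g_resp, target)
            if obs is None or gen is None:
                n_excluded += 1
                continue
            participants.add(pid)
            cond_ids.append(cond)
            for s in range(4):
                obs_pts[s].append(obs[s])
                gen_pts[s].append(gen[s])

        if len(participants) < 2:
            raise ValueError(
                f"correlation undefined for {task}/{group}: needs >= 2 "
                f"participants with usable cells, got {len(participants)}")
        stat_names = (("pc" if family == "cd" else "cv"), "rt_q25", "rt_q50", "rt_q75")
        cond_ids = np.array(cond_ids)
        for s, name in enumerate(stat_names):
            o = np.array(obs_pts[s])
            g = np.array(gen_pts[s])
            rows.append({
                "task": task, "age_group": group, "statistic": name,
                "r": _correlate(o, g, cond_ids, pooled),
                "n_participants": len(participants),
                "n_points": o.size, "n_excluded_cells": n_excluded,
            })
    return pd.DataFrame(rows)


def _correlate(obs, gen, cond_ids, pooled: bool) -> float:
    if pooled:
        if obs.size < 2 or np.std(obs) == 0 or np.std(gen) == 0:
            raise ValueError("correlation undefined: need >= 2 varying points "
                             "(at least two participants)")
        return float(np.corrcoef(obs, gen)[0, 1])
    zs = []
    for cond in np.unique(cond_ids):
        m = cond_ids == cond
        if m.sum() < 2 or np.std(obs[m]) == 0 or np.std(gen[m]) == 0:
            raise ValueError("correlation undefined within condition "
                             f"{cond!r}: need >= 2 varying points")
        r = np.clip(np.corrcoef(obs[m], gen[m])[0, 1], -0.999999, 0.999999)
        zs.append(np.arctanh(r))
    return float(np.tanh(np.mean(zs)))
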