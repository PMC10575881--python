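"""Forward simulators for the two-choice and circular diffusion processes.

Both simulators advance an Euler-Maruyama walk with step ``dt`` and apply a
Brownian-bridge boundary-crossing correction between steps: given surviving
distances d0, d1 to the absorbing boundary at the two step endpoints, the walk
is absorbed mid-step with probability exp(-2 d0 d1 / (s^2 dt)). Discrete
monitoring alone behaves like a boundary pushed outward by ~0.5826 s sqrt(dt),
which at dt = 1e-3 biases choice probabilities and exit times by far more than
the Monte-Carlo error of the large-n checks this module must satisfy; the
bridge correction reduces the discretisation bias to O(dt).

Decision times exceeding ``t_max`` are resampled and counted in the
diagnostics returned alongside cohort tables.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import (
    CONDITIONS,
    DMParams,
    StudyDesign,
    task_family,
    wrap_angle,
)
from .defaults import DEFAULT_HETEROGENEITY, GROUP_PARAM_MEANS

DEFAULT_DT = 0.001
DEFAULT_T_MAX = 30.0

# Hard floors applied by the clip-and-warn policy when sampled participant
# parameters leave the valid region.
_MIN_A = 0.05
_MIN_NU = 0.05
_MIN_TER = 0.0


@njit(cache=False)
def _choice_kernel(nu, a, ter, s, dt, t_max, seed):  # pragma: no cover - jitted
    n = nu.shape[0]
    correct = np.empty(n, np.bool_)
    rt = np.empty(n, np.float64)
    n_resampled = 0
    np.random.seed(seed)
    sqdt = math.sqrt(dt)
    for i in range(n):
        nui = nu[i]
        ai = a[i]
        si = s[i]
        drift = nui * dt
        sig = si * sqdt
        inv = 2.0 / (si * si * dt)
        while True:
            x = 0.5 * ai
            t = 0.0
            absorbed = False
            hit_upper = False
            while t < t_max:
                xn = x + drift + sig * np.random.standard_normal()
                t += dt
                if xn >= ai:
                    absorbed = True
                    hit_upper = True
                    break
                if xn <= 0.0:
                    absorbed = True
                    hit_upper = False
                    break
                # bridge crossing probabilities for either boundary; skip the
                # check when the crossing probability is below ~1e-14
                eu = (ai - x) * (ai - xn) * inv
                if eu < 32.0 and np.random.random() < math.exp(-eu):
                    absorbed = True
                    hit_upper = True
                    break
                el = x * xn * inv
                if el < 32.0 and np.random.random() < math.exp(-el):
                    absorbed = True
                    hit_upper = False
                    break
                x = xn
            if absorbed:
                correct[i] = hit_upper
                rt[i] = ter[i] + t
                break
            n_resampled += 1
    return correct, rt, n_resampled


@njit(cache=False)
def _circular_kernel(nu, a, ter, s, target, dt, t_max, seed):  # pragma: no cover
    n = nu.shape[0]
    resp = np.empty(n, np.float64)
    rt = np.empty(n, np.float64)
    n_resampled = 0
    np.random.seed(seed)
    sqdt = math.sqrt(dt)
    for i in range(n):
        ai = a[i]
        si = s[i]
        mx = nu[i] * math.cos(target[i]) * dt
        my = nu[i] * math.sin(target[i]) * dt
        sig = si * sqdt
        inv = 2.0 / (si * si * dt)
        a2 = ai * ai
        while True:
            x = 0.0
            y = 0.0
            d0 = ai
            t = 0.0
            absorbed = False
            while t < t_max:
                xn = x + mx + sig * np.random.standard_normal()
                yn = y + my + sig * np.random.standard_normal()
                t += dt
                r2 = xn * xn + yn * yn
                if r2 >= a2:
                    absorbed = True
                    x, y = xn, yn
                    break
                d1 = ai - math.sqrt(r2)
                e = d0 * d1 * inv
                if e < 32.0 and np.random.random() < math.exp(-e):
                    absorbed = True
                    x, y = xn, yn
                    break
                x, y = xn, yn
                d0 = d1
            if absorbed:
                resp[i] = math.atan2(y, x)
                rt[i] = ter[i] + t
                break
            n_resampled += 1
    return resp, rt, n_resampled


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _validate(params: DMParams, dt: float):
    if not isinstance(params, DMParams):
        params = DMParams(*params)
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return params


def simulate_choice_trials(
    params: DMParams,
    n: int,
    dt: float = DEFAULT_DT,
    rng=None,
    t_max: float = DEFAULT_T_MAX,
):
    """Simulate ``n`` two-choice trials; returns (correct bool[n], rt[n], n_resampled).

    The walk starts unbiased at a/2 and is absorbed at 0 (error) or a (correct).
    """
    params = _validate(params, dt)
    rng = _as_rng(rng)
    rep = np.full(n, 0.0)
    correct, rt, n_res = _choice_kernel(
        rep + params.nu, rep + params.a, rep + params.ter, rep + params.s,
        float(dt), float(t_max), _kernel_seed(rng),
    )
    return correct, rt, n_res


def simulate_choice_trial(params: DMParams, dt: float = DEFAULT_DT, rng=None):
    """One two-choice trial -> (correct, rt)."""
    c, rt, _ = simulate_choice_trials(params, 1, dt=dt, rng=rng)
    return bool(c[0]), float(rt[0])


def simulate_circular_trials(
    params: DMParams,
    target_angle,
    dt: float = DEFAULT_DT,
    rng=None,
    t_max: float = DEFAULT_T_MAX,
):
    """Simulate circular-report trials, one per target angle.

    The drift vector has magnitude nu and points at the target angle; the
    2-D walk starts at the disk center and is absorbed at radius a. Returns
    (response_angle[n] in [-pi, pi), rt[n], n_resampled).
    """
    params = _validate(params, dt)
    if params.nu < 0:
        raise ValueError("circular drift magnitude nu must be >= 0")
    rng = _as_rng(rng)
    target = wrap_angle(np.atleast_1d(np.asarray(target_angle, dtype=float)))
    if not np.all(np.isfinite(target)):
        raise ValueError("target angles must be finite")
    rep = np.zeros_like(target)
    resp, rt, n_res = _circular_kernel(
        rep + params.nu, rep + params.a, rep + params.ter, rep + params.s,
        target, float(dt), float(t_max), _kernel_seed(rng),
    )
    return wrap_angle(resp), rt, n_res


def simulate_circular_trial(params: DMParams, target_angle: float,
                            dt: float = DEFAULT_DT, rng=None):
    """One circular-report trial -> (response_angle, rt)."""
    resp, rt, _ = simulate_circular_trials(params, [target_angle], dt=dt, rng=rng)
    return float(resp[0]), float(rt[0])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _clip_params(nu, a, ter, clip_log: list, where: str):
    n_clip = 0
    for arr, lo in ((nu, _MIN_NU), (a, _MIN_A), (ter, _MIN_TER)):
        bad = arr < lo
        n_clip += int(bad.sum())
        arr[bad] = lo
    if n_clip:
        clip_log.append((where, n_clip))
        warnings.warn(
            f"{n_clip} sampled parameter value(s) in {where} fell outside the "
            "valid range and were clipped", stacklevel=3,
        )
    return nu, a, ter


def build_param_table(
    design: StudyDesign,
    group_means: dict | None = None,
    heterogeneity: dict | None = None,
    s: float = 1.0,
    rng=None,
    cell_noise_sd: dict | None = None,
) -> pd.DataFrame:
    """Draw one DMParams row per participant x task x condition.

    Participant deviations are drawn once per participant x task and shared by
    the two cue conditions (the cue effect shifts the cell mean), so the
    generated cohort carries genuine between-person variance for the
    hierarchical model's random effects to absorb. ``cell_noise_sd`` adds an
    independent per-cell jitter on top (emulating the estimation noise that
    per-cell EZ fits would contribute) for studies that consume the parameter
    table directly instead of simulating trials. Draws violating parameter
    invariants are clipped to the valid range with a warning.
    """
    group_means = GROUP_PARAM_MEANS if group_means is None else group_means
    het = dict(DEFAULT_HETEROGENEITY)
    if heterogeneity:
        het.update(heterogeneity)
    rng = _as_rng(design.seed if rng is None else rng)

    rows = []
    clip_log: list = []
    participants = design.participants
    for task_spec in design.tasks:
        task = task_spec.name
        for pid, group in participants:
            dev = {p: rng.normal(0.0, het[p]) for p in ("nu", "a", "ter")}
            for cond in CONDITIONS:
                vals = {}
                for p in ("nu", "a", "ter"):
                    base, eff = group_means[(task, group)][p]
                    mean = base if cond == "no_cue" else base + eff
                    vals[p] = mean + dev[p]
                    if cell_noise_sd:
                        vals[p] += rng.normal(0.0, cell_noise_sd.get(p, 0.0))
                rows.append(
                    {"participant": pid, "age_group": group, "task": task,
                     "condition": cond, "nu": vals["nu"], "a": vals["a"],
                     "ter": vals["ter"], "s": s}
                )
    table = pd.DataFrame(rows, columns=["participant", "age_group", "task",
                                        "condition", "nu", "a", "ter", "s"])
    nu = table["nu"].to_numpy().copy()
    a = table["a"].to_numpy().copy()
    ter = table["ter"].to_numpy().copy()
    _clip_params(nu, a, ter, clip_log, "param table")
    table["nu"], table["a"], table["ter"] = nu, a, ter
    return table


def _load_per_trial(load: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Realise a (possibly fractional) mean load as an integer load per trial.

    A fractional load mixes the two adjacent set sizes, with the fraction of
    ceil-load trials equal to the fractional part (5.4 -> 60% fives, 40% sixes).
    """
    lo = int(np.floor(load))
    frac = load - lo
    n_hi = int(round(frac * n))
    loads = np.full(n, lo, dtype=int)
    loads[:n_hi] = lo + 1
    rng.shuffle(loads)
    return loads


def generate_cohort(design: StudyDesign, params: pd.DataFrame | None = None,
                    seed: int | None = None, dt: float = DEFAULT_DT,
                    t_max: float = DEFAULT_T_MAX):
    """Generate trial tables for a full cohort.

    Returns a dict with keys 'choice' (CD trials), 'circular' (DE trials) and
    'diagnostics' (resample counts per task). Trial counts and the cue split
    are exact per participant; trial order is shuffled. Reproducible under the
    seed (same seed -> identical tables).
    """
    seed = design.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    if params is None:
        params = build_param_table(design, rng=np.random.default_rng(root.spawn(1)[0]))
    pkey = params.set_index(["participant", "task", "condition"])

    choice_rows = []
    circ_rows = []
    diagnostics = {}
    participants = design.participants
    task_seeds = root.spawn(len(design.tasks))
    for task_spec, tseed in zip(design.tasks, task_seeds):
        task = task_spec.name
        family = task_family(task)
        rng = np.random.default_rng(tseed)
        n_res_total = 0
        for pid, group in participants:
            n = task_spec.n_trials
            n_cue = int(round(task_spec.cue_proportion * n))
            conds = np.array(["no_cue"] * (n - n_cue) + ["retro_cue"] * n_cue)
            rng.shuffle(conds)
            loads = _load_per_trial(task_spec.load.get(group, 0.0), n, rng)
            for cond in CONDITIONS:
                mask = conds == cond
                m = int(mask.sum())
                if m == 0:
                    continue
                try:
                    prow = pkey.loc[(pid, task, cond)]
                except KeyError as exc:
                    raise KeyError(
                        f"parameter table has no cell for {(pid, task, cond)}"
                    ) from exc
                cell = DMParams(float(prow["nu"]), float(prow["a"]),
                                float(prow["ter"]), float(prow.get("s", 1.0)))
                if family == "cd":
                    correct, rt, n_res = simulate_choice_trials(
                        cell, m, dt=dt, rng=rng, t_max=t_max)
                    n_res_total += n_res
                    for ld, c, r in zip(loads[mask], correct, rt):
                        choice_rows.append(
                            {"participant": pid, "age_group": group, "task": task,
                             "condition": cond, "load": int(ld),
                             "correct": bool(c), "rt": float(r)})
                else:
                    target = rng.uniform(-np.pi, np.pi, size=m)
                    resp, rt, n_res = simulate_circular_trials(
                        cell, target, dt=dt, rng=rng, t_max=t_max)
                    n_res_total += n_res
                    for ld, th, ph, r in zip(loads[mask], target, resp, rt):
                        circ_rows.append(
                            {"participant": pid, "age_group": group, "task": task,
                             "condition": cond, "load": int(ld),
                             "response_angle": float(ph),
                             "target_angle": float(th), "rt": float(r)})
        diagnostics[task] = {"n_resampled": n_res_total}

    choice_cols = ["participant", "age_group", "task", "condition", "load",
                   "correct", "rt"]
    circ_cols = ["participant", "age_group", "task", "condition", "load",
                 "response_angle", "target_angle", "rt"]
    choice = pd.DataFrame(choice_rows, columns=choice_cols)
    circular = pd.DataFrame(circ_rows, columns=circ_cols)
    return {"choice": choice, "circular": circular, "diagnostics": diagnostics}


def cohort_to_csv_frame(cohort: dict) -> pd.DataFrame:
    """Concatenate choice and circular tables into the on-disk CSV layout.

    Angles are stored in degrees [0, 360); angle columns are empty for CD rows
    and the correctness column is empty for DE rows.
    """
    choice = cohort["choice"].copy()
    circular = cohort["circular"].copy()
    for col in ("response_deg", "target_deg"):
        choice[col] = np.nan
    choice["correct"] = choice["correct"].astype(float)
    circular["response_deg"] = np.degrees(circular.pop("response_angle")) % 360.0
    circular["target_deg"] = np.degrees(circular.pop("target_angle")) % 360.0
    circular["correct"] = np.nan
    cols = ["participant", "age_group", "task", "condition", "load",
            "correct", "rt", "response_deg", "target_deg"]
    return pd.concat([choice[cols], circular[cols]], ignore_index=True)
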