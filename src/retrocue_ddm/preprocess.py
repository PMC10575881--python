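"""Trial filtering and summary statistics feeding the EZ estimators.

Trimming runs per participant x task x condition cell: absolute RT bounds
first (change detection 0.1-7.5 s, delayed estimation 0.25-15 s), then a
single 3-SD pass around the cell mean of the surviving trials. For change
detection every RT-based step operates on correct trials only — incorrect
trials carry no usable RT and are always retained so that the proportion
correct keeps its denominator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ChoiceSummary, CircSummary, task_family, wrap_angle

ABS_BOUNDS = {"cd": (0.1, 7.5), "de": (0.25, 15.0)}
SD_CRITERION = 3.0
NORMAL_IQR = 1.349  # IQR/SD ratio of the normal distribution

_CELL = ["participant", "task", "condition"]


class CellError(ValueError):
    """A participant x condition cell cannot be summarised."""


def trim_rts(trials: pd.DataFrame, task_family_name: str,
             bounds: tuple | None = None, sd_criterion: float = SD_CRITERION):
    """Remove outlier RTs; returns (trimmed trials, trim report).

    ``task_family_name`` is 'cd' or 'de'. Removed trials leave the table
    entirely. The report has one row per cell with n_input,
    n_absolute_removed, n_sd_removed. Cells left empty are dropped with a
    warning.
    """
    if task_family_name not in ABS_BOUNDS:
        raise ValueError(f"task_family must be 'cd' or 'de', got {task_family_name!r}")
    lo, hi = ABS_BOUNDS[task_family_name] if bounds is None else bounds
    if not (0 < lo < hi):
        raise ValueError("trim bounds must be positive and ordered")

    is_cd = task_family_name == "cd"
    keep_masks = []
    report_rows = []
    for key, cell in trials.groupby(_CELL, sort=False):
        rt = cell["rt"].to_numpy(dtype=float)
        # RT-based removal applies to correct trials only in CD
        eligible = cell["correct"].to_numpy(dtype=bool) if is_cd else np.ones(len(cell), bool)
        ok_abs = ~eligible | ((rt >= lo) & (rt <= hi))
        n_abs = int((~ok_abs).sum())
        surv = eligible & ok_abs
        n_sd = 0
        if surv.sum() >= 2:
            m = rt[surv].mean()
            sd = rt[surv].std(ddof=1)
            ok_sd = ~surv | (np.abs(rt - m) <= sd_criterion * sd)
            n_sd = int((~ok_sd).sum())
        else:
            ok_sd = np.ones(len(cell), bool)
        keep = ok_abs & ok_sd
        keep_masks.append(pd.Series(keep, index=cell.index))
        report_rows.append(dict(zip(_CELL, key)) | {
            "n_input": len(cell), "n_absolute_removed": n_abs,
            "n_sd_removed": n_sd, "n_kept": int(keep.sum())})
        if keep.sum() == 0:
            warnings.warn(f"cell {key} empty after RT trimming; dropped", stacklevel=2)
    if not keep_masks:
        return trials.iloc[0:0].copy(), pd.DataFrame(
            columns=_CELL + ["n_input", "n_absolute_removed", "n_sd_removed", "n_kept"])
    keep_all = pd.concat(keep_masks).reindex(trials.index, fill_value=False)
    return trials[keep_all].copy(), pd.DataFrame(report_rows)


def correct_edge_accuracy(pc: float, n: int) -> float:
    """Nudge degenerate accuracies off the boundary of the logit's domain.

    pc in {0, 0.5} gains 1/(2n); pc = 1 loses 1/(2n); anything else is
    returned unchanged. n must be the post-trim trial count of the same cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= pc <= 1.0:
        raise ValueError(f"pc must lie in [0, 1], got {pc}")
    if pc == 0.0 or pc == 0.5:
        return pc + 1.0 / (2 * n)
    if pc == 1.0:
        return pc - 1.0 / (2 * n)
    return pc


def summarize_choice(trials: pd.DataFrame) -> ChoiceSummary:
    """Summaries of one trimmed CD cell: pc over all trials, median and
    sample variance (n-1) of correct-trial RTs. Raises CellError when no
    correct trials remain or the correct-RT variance is undefined."""
    n = len(trials)
    if n == 0:
        raise CellError("empty cell")
    correct = trials["correct"].to_numpy(dtype=bool)
    pc = float(correct.mean())
    crt = trials.loc[correct, "rt"].to_numpy(dtype=float)
    if crt.size == 0:
        raise CellError("no correct trials in cell")
    if crt.size < 2:
        raise CellError("single correct trial: RT variance undefined")
    return ChoiceSummary(pc=pc, mrt=float(np.median(crt)),
                         vrt=float(np.var(crt, ddof=1)), n=n)


def circular_dispersion(errors: np.ndarray):
    """(circular variance, mean absolute deviation) of wrapped errors."""
    cv = 1.0 - float(np.abs(np.exp(1j * errors).mean()))
    return min(max(cv, 0.0), 1.0), float(np.abs(errors).mean())


def summarize_circular(trials: pd.DataFrame) -> CircSummary:
    """Summaries of one trimmed DE cell.

    Report error is response - target wrapped to the principal domain;
    cv = 1 - mean resultant length; mad = mean |error|; mrt = median RT of
    all trials; vrt = (IQR/1.349)^2 with linear-interpolation quartiles.
    Cells with n < 4 get vrt_reliable=False.
    """
    n = len(trials)
    if n == 0:
        raise CellError("empty cell")
    err = wrap_angle(trials["response_angle"].to_numpy(dtype=float)
                     - trials["target_angle"].to_numpy(dtype=float))
    cv, mad = circular_dispersion(err)
    rt = trials["rt"].to_numpy(dtype=float)
    q25, q75 = np.percentile(rt, [25, 75])
    return CircSummary(cv=cv, mad=mad, mrt=float(np.median(rt)),
                       vrt=float(((q75 - q25) / NORMAL_IQR) ** 2), n=n,
                       vrt_reliable=n >= 4)


def cv_report_scale(cv: float, convention: str = "percent"):
    """Convert the internal circular variance in [0, 1] to a reporting scale.

    Published dispersion tables sometimes print values well above 1; the two
    plausible conventions are 'percent' (cv x 100) and 'degrees'
    (circular SD sqrt(-2 ln(1-cv)) expressed in degrees).
    """
    if convention == "percent":
        return 100.0 * cv
    if convention == "degrees":
        r = max(1.0 - cv, 1e-12)
        return float(np.degrees(np.sqrt(-2.0 * np.log(r))))
    raise ValueError(f"unknown convention {convention!r}")


def summarize_trials(trials: pd.DataFrame, trim: bool = True):
    """Trim and summarise a mixed trial table; returns (summaries, trim report).

    One summary row per participant x task x condition with a status column;
    cells that cannot be summarised become status != 'ok' rows instead of
    aborting the batch. CD accuracies are edge-corrected (pc column; pc_raw
    keeps the uncorrected value).
    """
    meta_cols = [c for c in ("age_group",) if c in trials.columns]
    frames = []
    reports = []
    for fam in ("cd", "de"):
        fam_trials = trials[trials["task"].map(task_family) == fam]
        if fam_trials.empty:
            continue
        if trim:
            fam_trials, rep = trim_rts(fam_trials, fam)
            reports.append(rep)
        for key, cell in fam_trials.groupby(_CELL, sort=False):
            row = dict(zip(_CELL, key))
            for mc in meta_cols:
                row[mc] = cell[mc].iloc[0]
            row["family"] = fam
            try:
                if fam == "cd":
                    s = summarize_choice(cell)
                    row |= {"n": s.n, "pc_raw": s.pc,
                            "pc": correct_edge_accuracy(s.pc, s.n),
                            "mrt": s.mrt, "vrt": s.vrt, "status": "ok"}
                else:
                    s = summarize_circular(cell)
                    row |= {"n": s.n, "cv": s.cv, "mad": s.mad, "mrt": s.mrt,
                            "vrt": s.vrt,
                            "status": "ok" if s.vrt_reliable else "vrt_unreliable"}
            except CellError as exc:
                row |= {"n": len(cell), "status": f"error: {exc}"}
            frames.append(row)
    summaries = pd.DataFrame(frames)
    report = (pd.concat(reports, ignore_index=True) if reports
              else pd.DataFrame())
    return summaries, report
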