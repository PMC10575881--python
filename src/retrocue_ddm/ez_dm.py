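"""Closed-form EZ estimation for the two-choice diffusion model.

The estimator maps the cell-level moments (proportion correct pc, a central
RT of correct trials mrt, and their sample variance vrt) to drift rate nu,
boundary separation a and nondecision time ter, assuming an unbiased start
point at a/2 and no across-trial parameter variability. With
L = logit(pc) and y = -nu*a/s^2:

    pc  = 1 / (1 + e^y)
    mdt = (a / (2 nu)) * (1 - e^y) / (1 + e^y)
    vrt = L (L pc^2 - L pc + pc - 1/2) (s / nu)^4

which invert in closed form. The robust variant used throughout this package
feeds the *median* of correct RTs into the mrt slot (the variance stays the
ordinary n-1 sample variance). Subtracting the model's mean decision time
from a median RT would push the full median-mean gap of the right-skewed
first-passage distribution (easily 10% of the decision time) into ter, so by
default the inverse subtracts the model-implied *median* decision time,
computed from the first-passage CDF at the estimated drift and boundary;
``ter_reference='mean'`` restores the exact algebraic inverse of the mean
forward equations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import DMParams


class EstimationError(ValueError):
    """The EZ moments lie outside the estimator's domain."""


def wiener_decision_cdf(t: float, nu: float, a: float, s: float = 1.0) -> float:
    """CDF of the decision time for an unbiased (z = a/2) two-boundary walk.

    With an unbiased start the decision-time distribution is the same for
    correct and error responses, so this is also the correct-RT decision-time
    law. Evaluated as 1 minus the survival series (the termwise-integrated
    constant part telescopes to the total absorption probability, 1), whose
    terms decay like exp(-k^2 pi^2 s^2 t / (2 a^2)) — rapidly convergent for
    any t bounded away from 0.
    """
    if t <= 0:
        return 0.0
    tau = math.pi**2 * s**2 * t / (2.0 * a**2)  # decay rate of the k=1 term
    if tau < 1e-4:
        # survival ~ 1 to far beyond double precision
        return 0.0
    k_max = max(8, int(math.sqrt(45.0 / tau)) + 2)
    z = a / 2.0
    surv = 0.0
    for v, zz in ((nu, z), (-nu, a - z)):
        pref = math.pi * s**2 / a**2 * math.exp(-v * zz / s**2)
        acc = 0.0
        for k in range(1, k_max + 1):
            sk = math.sin(k * math.pi * zz / a)
            if sk == 0.0:
                continue
            lam = 0.5 * ((v / s) ** 2 + (k * math.pi * s / a) ** 2)
            acc += k * sk / lam * math.exp(-lam * t)
        surv += pref * acc
    return min(max(1.0 - surv, 0.0), 1.0)


def wiener_decision_median(nu: float, a: float, s: float = 1.0) -> float:
    """Median decision time of the unbiased two-boundary walk (root of the CDF)."""
    if nu != 0:
        y = -nu * a / s**2
        mean = (a / (2.0 * nu)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    else:
        mean = a**2 / (4.0 * s**2)
    hi = 4.0 * mean + 1.0
    return float(optimize.brentq(
        lambda t: wiener_decision_cdf(t, nu, a, s) - 0.5, 1e-12, hi,
        xtol=1e-14, rtol=8.9e-16))


def ez_forward(params: DMParams):
    """Expected (pc, mdt, vrt) for a parameter triple.

    Returns a dict with keys pc, mdt (mean decision time), mrt (= ter + mdt),
    mdt_median, mrt_median, vrt. Requires nu != 0: at zero drift pc = 1/2 and
    the logit inversion is undefined.
    """
    if params.nu == 0:
        raise EstimationError("ez_forward undefined at nu = 0 (pc = 1/2)")
    nu, a, s = params.nu, params.a, params.s
    y = -nu * a / s**2
    pc = 1.0 / (1.0 + math.exp(y))
    mdt = (a / (2.0 * nu)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    L = math.log(pc / (1.0 - pc))
    vrt = L * (L * pc**2 - L * pc + pc - 0.5) * (s / nu) ** 4
    mdt_med = wiener_decision_median(nu, a, s)
    return {"pc": pc, "mdt": mdt, "mrt": params.ter + mdt, "vrt": vrt,
            "mdt_median": mdt_med, "mrt_median": params.ter + mdt_med}


def ez_inverse(pc: float, mrt: float, vrt: float, s: float = 1.0,
               ter_reference: str = "median") -> DMParams:
    """Closed-form inverse: moments -> DMParams.

    pc must be strictly inside (0, 1) and off 1/2 (edge-correct upstream);
    vrt must be positive. ter_reference chooses which model decision-time
    statistic is subtracted from mrt: 'median' (default; consistent when mrt
    is the empirical median of correct RTs) or 'mean' (the exact algebraic
    inverse of ez_forward's mean equations). Negative ter estimates are
    legitimate on noisy cells and are preserved, never clipped.
    """
    if not 0.0 < pc < 1.0:
        raise EstimationError(f"pc must lie strictly in (0, 1), got {pc}")
    if pc == 0.5:
        raise EstimationError("pc = 1/2 exactly: drift direction unidentified")
    if not vrt > 0:
        raise EstimationError(f"vrt must be > 0, got {vrt}")
    if not s > 0:
        raise EstimationError("s must be > 0")
    if ter_reference not in ("median", "mean"):
        raise ValueError(f"unknown ter_reference {ter_reference!r}")
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    nu = math.copysign(1.0, pc - 0.5) * s * x**0.25
    a = s**2 * L / nu
    if ter_reference == "median":
        mdt = wiener_decision_median(nu, a, s)
    else:
        y = -nu * a / s**2
        mdt = (a / (2.0 * nu)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    ter = mrt - mdt
    return _make_params(nu, a, ter, s)


def _make_params(nu, a, ter, s) -> DMParams:
    # DMParams forbids ter < 0, but a negative EZ nondecision estimate is a
    # meaningful diagnostic that must be preserved; construct around the check.
    p = DMParams(nu, a, max(ter, 0.0), s)
    if ter < 0:
        object.__setattr__(p, "ter", float(ter))
    return p


def estimate_choice_params(summaries: pd.DataFrame, s: float = 1.0) -> pd.DataFrame:
    """Batch EZ estimation over a CD summaries table.

    Consumes rows with columns pc, mrt, vrt (plus identifiers); emits one row
    per input row with nu, a, ter, s and a status/reason column. Estimation
    failures yield missing-value rows, never abort the batch, so the
    downstream hierarchical model always sees a rectangular table.
    """
    id_cols = [c for c in ("participant", "age_group", "task", "condition")
               if c in summaries.columns]
    out = []
    for _, row in summaries.iterrows():
        rec = {c: row[c] for c in id_cols}
        rec["s"] = s
        status = row.get("status", "ok")
        if isinstance(status, str) and status.startswith("error"):
            rec |= {"nu": np.nan, "a": np.nan, "ter": np.nan, "status": status}
            out.append(rec)
            continue
        try:
            p = ez_inverse(float(row["pc"]), float(row["mrt"]),
                           float(row["vrt"]), s=s)
            rec |= {"nu": p.nu, "a": p.a, "ter": p.ter,
                    "status": "ok" if p.ter >= 0 else "ok_negative_ter"}
        except (EstimationError, ValueError, KeyError) as exc:
            rec |= {"nu": np.nan, "a": np.nan, "ter": np.nan,
                    "status": f"error: {exc}"}
        out.append(rec)
    return pd.DataFrame(out)
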