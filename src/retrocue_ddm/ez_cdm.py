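"""Circular diffusion model numerics and the EZ-style moment estimator.

Model: a 2-D Wiener process with diffusion coefficient s starts at the center
of a disk of radius a; the drift vector has magnitude nu and points at the
target angle. The hitting angle is von Mises around the target with
concentration kappa = a*nu/s^2 and is independent of the hitting time. In
scaled units (a = s = 1) the zero-drift first-passage density is the classical
Bessel-zero series

    f0(t) = sum_k c_k exp(-j0k^2 t / 2),      c_k = j0k / J1(j0k),

with j0k the ascending zeros of J0, and with drift the decision-time density
is f(t) = I0(kappa) exp(-kappa^2 t / 2) f0(t). Termwise integration gives the
raw moments as exponential integrals; equivalently the Laplace transform
E[exp(-uT)] = 1 / I0(sqrt(2u)) yields closed forms in Bessel-function ratios:

    m_k(kappa) = I1(kappa) / (kappa I0(kappa))
    v_k(kappa) = (R^2 - 1 + 2 R / kappa) / kappa^2,   R = I1/I0,

with m_k(0) = 1/2 and v_k(0) = 1/8. The closed forms (evaluated with
exponentially-scaled Bessel functions, stable beyond kappa = 500) are the
default; the truncated series — whose alternating terms cancel
catastrophically for large kappa — is kept as an independent validation path
with Euler-type acceleration of its partial sums.

Physical decision times scale as (a^2/s^2) x (dimensionless function of
kappa), which is what the inverse estimator exploits.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, special

from .datatypes import DMParams
from .ez_dm import EstimationError, _make_params

MAX_BESSEL_ZEROS = 500


@lru_cache(maxsize=8)
def bessel_j0_zeros(n: int = MAX_BESSEL_ZEROS) -> np.ndarray:
    """First n ascending zeros of J0 (scipy's Newton-refined values, ~1e-14)."""
    if not 1 <= n <= MAX_BESSEL_ZEROS:
        raise ValueError(f"zero count must lie in [1, {MAX_BESSEL_ZEROS}]")
    return special.jn_zeros(0, n)


def _series_coefficients(n: int):
    j0 = bessel_j0_zeros(n)
    return j0, j0 / special.j1(j0)


def _accelerated_sum(terms: np.ndarray, levels: int = 14) -> float:
    """Euler-type acceleration: iterated averaging of the trailing partial sums.

    The series here are alternating with slowly decaying magnitude; direct
    truncation converges like j^(-1/2) for the p=0 sum, while iterated
    averaging reaches machine precision with a few hundred terms.
    """
    s = np.cumsum(terms)
    tail = s[-(levels + 1):].astype(float)
    while tail.size > 1:
        tail = 0.5 * (tail[1:] + tail[:-1])
    return float(tail[0])


def mean_resultant_length(kappa) -> float:
    """R(kappa) = I1/I0, overflow-safe via exponentially-scaled Bessels."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.where(kappa > 0, special.i1e(kappa) / special.i0e(np.maximum(kappa, 1e-300)), 0.0)
    return float(out) if out.ndim == 0 else out


def kappa_from_cv(cv: float) -> float:
    """Von Mises concentration from the circular variance of report errors.

    Solves I1(k)/I0(k) = 1 - cv by bracketed root finding. cv = 1 maps to
    k = 0 (uniform errors); cv <= 0 is rejected (unbounded concentration).
    """
    if cv > 1.0:
        raise EstimationError(f"circular variance cannot exceed 1, got {cv}")
    if cv <= 0.0:
        raise EstimationError("cv <= 0: unbounded concentration")
    if cv == 1.0:
        return 0.0
    rbar = 1.0 - cv
    hi = 2.0
    while mean_resultant_length(hi) < rbar:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise EstimationError("concentration solve failed to bracket")
    return float(optimize.brentq(lambda k: mean_resultant_length(k) - rbar,
                                 0.0, hi, xtol=1e-12, rtol=1e-14))


def laplace_transform_series(kappa: float, n_zeros: int = MAX_BESSEL_ZEROS) -> float:
    """sum_k c_k * 2/(j0k^2 + kappa^2), accelerated; equals 1/I0(kappa)."""
    j0, c = _series_coefficients(n_zeros)
    return _accelerated_sum(c * 2.0 / (j0**2 + kappa**2))


def fpt_scaled_moments(kappa: float, method: str = "closed",
                       n_zeros: int = MAX_BESSEL_ZEROS):
    """Scaled decision-time mean and variance (m_k, v_k) at a = s = 1.

    method='closed' uses the Bessel-ratio forms (default, stable for any
    kappa >= 0); method='series' sums the Bessel-zero expansion
    E[T^p] = I0(k) sum_k c_k p! (2/(j0k^2+k^2))^(p+1) with acceleration —
    accurate to ~1e-12 for kappa <= 15 and used as a cross-check.
    """
    if not math.isfinite(kappa) or kappa < 0:
        raise EstimationError(f"kappa must be finite and >= 0, got {kappa}")
    if method == "closed":
        if kappa == 0.0:
            return 0.5, 0.125
        R = mean_resultant_length(kappa)
        m = R / kappa
        v = (R * R - 1.0 + 2.0 * R / kappa) / kappa**2
        return float(m), float(v)
    if method == "series":
        j0, c = _series_coefficients(n_zeros)
        lam = j0**2 + kappa**2
        i0 = special.i0(kappa)
        if not math.isfinite(i0):
            raise EstimationError("kappa too large for the series path; use method='closed'")
        m = i0 * _accelerated_sum(c * (2.0 / lam) ** 2)
        et2 = i0 * _accelerated_sum(c * 2.0 * (2.0 / lam) ** 3)
        return float(m), float(et2 - m * m)
    raise ValueError(f"unknown method {method!r}")


def cdm_decision_cdf_scaled(t: float, kappa: float,
                            n_zeros: int = MAX_BESSEL_ZEROS) -> float:
    """CDF of the scaled (a = s = 1) circular decision time.

    Termwise integral of f(t) = I0(k) exp(-k^2 t/2) f0(t):
    F(t) = 1 - I0(k) sum_k c_k exp(-(j0k^2+k^2) t/2) * 2/(j0k^2+k^2),
    using the Laplace normalisation identity for the constant part. The
    alternating tail is Euler-accelerated. Reliable for kappa <~ 15, which
    covers any empirically plausible concentration here.
    """
    if t <= 0:
        return 0.0
    j0, c = _series_coefficients(n_zeros)
    lam = j0**2 + kappa**2
    surv = special.i0(kappa) * _accelerated_sum(
        c * np.exp(-0.5 * lam * t) * 2.0 / lam)
    return min(max(1.0 - surv, 0.0), 1.0)


def cdm_decision_quantile_scaled(kappa: float, p: float) -> float:
    """p-quantile of the scaled circular decision time (root of the series CDF).

    Falls back to a normal approximation around the closed-form moments for
    kappa > 15, where the alternating series loses precision; at such extreme
    concentrations the decision-time distribution is nearly symmetric anyway.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    m, v = fpt_scaled_moments(kappa)
    if kappa > 15.0:
        from scipy.stats import norm

        return max(m + norm.ppf(p) * math.sqrt(v), 1e-12)
    return float(optimize.brentq(
        lambda t: cdm_decision_cdf_scaled(t, kappa) - p, 1e-12, 8.0 * m + 1.0,
        xtol=1e-14, rtol=8.9e-16))


def cdm_decision_median_scaled(kappa: float) -> float:
    """Median of the scaled circular decision time."""
    return cdm_decision_quantile_scaled(kappa, 0.5)


def cdm_decision_iqr_scaled(kappa: float) -> float:
    """Interquartile range of the scaled circular decision time."""
    return (cdm_decision_quantile_scaled(kappa, 0.75)
            - cdm_decision_quantile_scaled(kappa, 0.25))


def vm_mean_abs_dev(kappa: float) -> float:
    """Mean absolute deviation E|theta| of a von Mises(0, kappa), by quadrature."""
    if kappa < 0:
        raise EstimationError("kappa must be >= 0")
    if kappa == 0.0:
        return math.pi / 2.0
    # density with scaled normalisation to avoid overflow at large kappa
    norm = 2.0 * math.pi * special.i0e(kappa)
    val, _ = integrate.quad(
        lambda th: th * math.exp(kappa * (math.cos(th) - 1.0)) / norm,
        0.0, math.pi, limit=200)
    return 2.0 * val


def ezcdm_forward(params: DMParams):
    """Expected (cv, mad, mdt, vdt) under the circular model; mrt = ter + mdt.

    Also carries mdt_median/mrt_median (the model's median decision time),
    the statistic matched by the default inverse.
    """
    if params.nu < 0:
        raise EstimationError("circular drift magnitude nu must be >= 0")
    kappa = params.kappa
    m, v = fpt_scaled_moments(kappa)
    scale = (params.a / params.s) ** 2
    med = scale * cdm_decision_median_scaled(kappa)
    iqr = scale * cdm_decision_iqr_scaled(kappa)
    return {
        "cv": 1.0 - mean_resultant_length(kappa),
        "mad": vm_mean_abs_dev(kappa),
        "mdt": scale * m,
        "mrt": params.ter + scale * m,
        "mdt_median": med,
        "mrt_median": params.ter + med,
        "vdt": scale**2 * v,
        "vrt_iqr": (iqr / 1.349) ** 2,
        "kappa": kappa,
    }


def ezcdm_inverse(cv: float, mrt: float, vrt: float, s: float = 1.0,
                  ter_reference: str = "median",
                  scale_reference: str = "iqr") -> DMParams:
    """Moment-matching inverse for the circular model.

    kappa comes from the circular variance, the boundary radius from the RT
    dispersion, drift from kappa = a nu / s^2, and ter from the RT median
    minus the implied decision time. The default references match the robust
    statistics the pipeline actually feeds in: mrt is an empirical median, so
    the model *median* decision time is subtracted (ter_reference='mean'
    matches the mean instead), and vrt is a normalized-IQR variance, so the
    boundary matches the model's decision-time IQR — equating a
    normalized-IQR to the true variance v_k of the right-skewed
    first-passage law would bias the boundary low by ~10%
    (scale_reference='variance' restores the plain moment match). mad is not
    consumed: {cv, mrt, vrt} already identify (kappa, a, ter) exactly.
    Negative ter is preserved and flagged by the batch wrapper, never clipped.
    """
    if not vrt > 0:
        raise EstimationError(f"vrt must be > 0, got {vrt}")
    if not s > 0:
        raise EstimationError("s must be > 0")
    if ter_reference not in ("median", "mean"):
        raise ValueError(f"unknown ter_reference {ter_reference!r}")
    if scale_reference not in ("iqr", "variance"):
        raise ValueError(f"unknown scale_reference {scale_reference!r}")
    kappa = kappa_from_cv(cv)
    if kappa == 0.0:
        raise EstimationError("cv = 1 gives kappa = 0: nu = 0 and a unidentified")
    m, v = fpt_scaled_moments(kappa)
    if scale_reference == "iqr":
        # vrt = (IQR_obs/1.349)^2 and IQR scales as (a/s)^2 * iqr_k(kappa)
        a = s * math.sqrt(1.349 * math.sqrt(vrt) / cdm_decision_iqr_scaled(kappa))
    else:
        a = s * (vrt / v) ** 0.25
    nu = kappa * s**2 / a
    ref = cdm_decision_median_scaled(kappa) if ter_reference == "median" else m
    ter = mrt - (a / s) ** 2 * ref
    return _make_params(nu, a, ter, s)


def estimate_circular_params(summaries, s: float = 1.0):
    """Batch EZ-CDM estimation over a DE summaries table (see estimate_choice_params)."""
    import pandas as pd

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
            p = ezcdm_inverse(float(row["cv"]), float(row["mrt"]),
                              float(row["vrt"]), s=s)
            flag = "ok" if p.ter >= 0 else "ok_negative_ter"
            if status == "vrt_unreliable":
                flag = "ok_vrt_unreliable" if p.ter >= 0 else "ok_negative_ter"
            rec |= {"nu": p.nu, "a": p.a, "ter": p.ter, "status": flag}
        except (EstimationError, ValueError, KeyError) as exc:
            rec |= {"nu": np.nan, "a": np.nan, "ter": np.nan,
                    "status": f"error: {exc}"}
        out.append(rec)
    return pd.DataFrame(out)
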