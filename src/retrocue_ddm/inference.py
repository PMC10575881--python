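"""Group-level Bayesian estimation of retro-cue and age effects.

Each diffusion parameter (drift rate, nondecision time, boundary separation)
is analysed separately with a Bayesian linear mixed model on the per-cell EZ
estimates. Fixed effects form the saturated design in the four effect-coded
(+-0.5) binary predictors — age group, retrieval paradigm (CD vs. DE), memory
material (color vs. orientation) and cue condition — so each of the 16 cell
means is a linear combination of the coefficients and every reported contrast
is a raw parameter-scale difference. Random structure: by-participant
intercepts plus by-participant slopes for paradigm and material, with
independent variances.

Non-intercept fixed effects carry normal(0, 0.5) priors; the intercept a
vague normal(0, 5) (a grand-mean prior of SD 0.5 would bias every cell mean,
and the intercept is never tested). Variances get inverse-gamma(2, 0.05)
priors. The model is conditionally conjugate throughout, so posterior draws
come from a blocked Gibbs sampler; convergence is asserted with split-R-hat.

Bayes factors for point nulls use the Savage-Dickey density ratio: the
implied prior of a contrast c'beta is normal with SD 0.5*||c||, and BF10 is
the prior over posterior density at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AGE_GROUPS, EffectEstimate, TASKS, task_family

OUTCOMES = ("nu", "ter", "a")

_FACTORS = ("age", "paradigm", "material", "cue")

# effect codes, +-0.5 so a main effect reads as a condition difference
_CODES = {
    "age": {"younger": 0.5, "older": -0.5},
    "paradigm": {"de": 0.5, "cd": -0.5},
    "material": {"color": 0.5, "orientation": -0.5},
    "cue": {"retro_cue": 0.5, "no_cue": -0.5},
}

# all 16 interaction subsets of the four factors, intercept first
_TERMS = [()]
for _f in _FACTORS:
    _TERMS += [t + (_f,) for t in _TERMS]
_TERMS.sort(key=len)
TERM_NAMES = [":".join(t) if t else "intercept" for t in _TERMS]


class ConvergenceError(RuntimeError):
    """MCMC chains failed the split-R-hat criterion."""


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 500
    samples: int = 2000
    rhat_threshold: float = 1.05
    seed: int = 0
    # the full-reproduction budget of the emulated analysis is
    # McmcConfig(chains=4, warmup=2000, samples=10000)

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-R-hat")
        if self.rhat_threshold < 1.0:
            raise ValueError("rhat_threshold must be >= 1")
        if self.warmup < 0 or self.samples < 1:
            raise ValueError("warmup must be >= 0 and samples >= 1")


def factor_codes(age_group: str, task: str, condition: str) -> dict:
    material = task.split("_")[0]
    return {
        "age": _CODES["age"][age_group],
        "paradigm": _CODES["paradigm"][task_family(task)],
        "material": _CODES["material"][material],
        "cue": _CODES["cue"][condition],
    }


def design_row(age_group: str, task: str, condition: str) -> np.ndarray:
    """Fixed-effect design row (16,) for one cell of the 2x2x2x2 layout."""
    codes = factor_codes(age_group, task, condition)
    return np.array([np.prod([codes[f] for f in t]) if t else 1.0 for t in _TERMS])


def contrast_vector(cells) -> np.ndarray:
    """Coefficient-space contrast from weighted cells [(age, task, cond, w), ...]."""
    c = np.zeros(len(_TERMS))
    for age, task, cond, w in cells:
        c += w * design_row(age, task, cond)
    return c


def implied_prior_sd(c: np.ndarray, prior_sd: float = 0.5) -> float:
    """Prior SD of the contrast c'beta under independent N(0, prior_sd) coefficients.

    Only valid for genuine contrasts (zero intercept weight), since the
    intercept carries a different, vague prior.
    """
    if abs(c[0]) > 1e-12:
        raise ValueError("contrast involves the intercept; its prior is not defined by prior_sd")
    return prior_sd * float(np.linalg.norm(c[1:]))


@dataclass
class HierarchicalPosterior:
    """Posterior draws from the blocked Gibbs sampler."""

    beta: np.ndarray                 # (chains, draws, 16)
    sigma: np.ndarray                # (chains, draws) residual SD
    tau: np.ndarray                  # (chains, draws, 3) random-effect SDs
    term_names: list
    outcome: str
    prior_sd: float
    rhat: pd.Series = field(repr=False)
    config: McmcConfig = None
    n_rows: int = 0
    n_participants: int = 0
    n_dropped: int = 0

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def contrast_draws(self, c: np.ndarray) -> np.ndarray:
        return self.beta_flat @ c


def _build_design(param_table: pd.DataFrame, outcome: str):
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    need = {"participant", "age_group", "task", "condition", outcome}
    missing = need - set(param_table.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns {sorted(missing)}")
    tab = param_table.copy()
    ok = np.isfinite(pd.to_numeric(tab[outcome], errors="coerce"))
    n_dropped = int((~ok).sum())
    tab = tab[ok]
    if tab.empty:
        raise ValueError("no usable rows in parameter table")

    y = tab[outcome].to_numpy(dtype=float)
    X = np.stack([design_row(r.age_group, r.task, r.condition)
                  for r in tab.itertuples()])
    codes = np.array([[1.0,
                       _CODES["paradigm"][task_family(r.task)],
                       _CODES["material"][r.task.split("_")[0]]]
                      for r in tab.itertuples()])
    pid, _ = pd.factorize(tab["participant"], sort=True)
    return y, X, codes, pid, n_dropped


def _gibbs_chain(y, X, Z, pid, n_p, prior_prec_beta, cfg_tuple, rng):
    """One Gibbs chain; returns (beta, sigma, tau) post-warmup draws.

    The fixed-effect block is collapsed: beta is drawn from
    p(beta | y, sigma, tau) with the random effects integrated out (Woodbury
    on the per-participant marginal covariance), which removes the slow
    beta <-> b random walk of the naive two-block sampler.
    """
    warmup, samples = cfg_tuple
    n, k = X.shape
    q = Z.shape[1]
    a0, b0 = 2.0, 0.05  # inverse-gamma hyperparameters for all variances

    XtX = X.T @ X
    Xty = X.T @ y
    # per-participant cross products
    ZtZ = np.zeros((n_p, q, q))
    np.add.at(ZtZ, pid, Z[:, :, None] * Z[:, None, :])
    XtZ = np.zeros((n_p, k, q))
    np.add.at(XtZ, pid, X[:, :, None] * Z[:, None, :])
    Zty = np.zeros((n_p, q))
    np.add.at(Zty, pid, Z * y[:, None])

    beta = np.linalg.solve(XtX + np.eye(k), Xty)  # ridge start
    b = np.zeros((n_p, q))
    tau2 = np.full(q, 0.04)
    resid0 = y - X @ beta
    sigma2 = max(float(np.var(resid0)), 1e-4)

    out_beta = np.empty((samples, k))
    out_sigma = np.empty(samples)
    out_tau = np.empty((samples, q))
    for it in range(warmup + samples):
        # fixed effects | variances (random effects marginalised out):
        # V_p = sigma2 I + Z_p diag(tau2) Z_p'; Woodbury gives
        # X'V^-1X = X'X/s2 - 1/s4 * sum_p XZ_p M_p XZ_p',
        # M_p = (diag(1/tau2) + Z_p'Z_p/s2)^-1
        M = np.linalg.inv(np.diag(1.0 / tau2)[None, :, :] + ZtZ / sigma2)
        A = (XtX / sigma2 + np.diag(prior_prec_beta)
             - np.einsum("pij,pjl,pml->im", XtZ, M, XtZ) / sigma2**2)
        rhs = Xty / sigma2 - np.einsum("pij,pjl,pl->i", XtZ, M, Zty) / sigma2**2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, rhs)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(k))

        # random effects | fixed effects, variances (batched 3x3 solves)
        r = y - X @ beta
        Ztr = np.zeros((n_p, q))
        np.add.at(Ztr, pid, Z * r[:, None])
        G = ZtZ / sigma2 + np.diag(1.0 / tau2)[None, :, :]
        Lb = np.linalg.cholesky(G)
        mean_b = np.linalg.solve(G, Ztr[:, :, None] / sigma2)[:, :, 0]
        eps = rng.standard_normal((n_p, q, 1))
        b = mean_b + np.linalg.solve(np.transpose(Lb, (0, 2, 1)), eps)[:, :, 0]

        # variances
        tau2 = 1.0 / rng.gamma(a0 + 0.5 * n_p, 1.0 / (b0 + 0.5 * (b**2).sum(axis=0)))
        resid = r - np.einsum("nq,nq->n", Z, b[pid])
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * float(resid @ resid)))

        if it >= warmup:
            j = it - warmup
            out_beta[j] = beta
            out_sigma[j] = math.sqrt(sigma2)
            out_tau[j] = np.sqrt(tau2)
    return out_beta, out_sigma, out_tau


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of draws shaped (chains, draws)."""
    c, d = x.shape
    half = d // 2
    if half < 2:
        return np.nan
    halves = x[:, : 2 * half].reshape(c * 2, half)
    m = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    bvar = half * m.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + bvar / half
    return float(np.sqrt(var_plus / w))


def fit_hierarchical_effects(
    param_table: pd.DataFrame,
    outcome: str,
    cfg: McmcConfig | None = None,
    prior_sd: float = 0.5,
    on_nonconvergence: str = "raise",
) -> HierarchicalPosterior:
    """Fit the hierarchical mixed model for one diffusion parameter.

    ``param_table`` is the rectangular per-participant/task/condition EZ
    output; rows whose outcome is missing (estimation failures) are dropped
    with their count recorded. Raises ConvergenceError (with the full R-hat
    table in the message) when any fixed effect exceeds the split-R-hat
    threshold, unless on_nonconvergence='warn'.
    """
    cfg = cfg or McmcConfig()
    y, X, Z, pid, n_dropped = _build_design(param_table, outcome)
    n_p = int(pid.max()) + 1
    k = X.shape[1]
    prior_prec = np.full(k, 1.0 / prior_sd**2)
    prior_prec[0] = 1.0 / 5.0**2  # vague intercept prior

    root = np.random.SeedSequence(cfg.seed)
    chains_beta, chains_sigma, chains_tau = [], [], []
    for ss in root.spawn(cfg.chains):
        bdraws, sdraws, tdraws = _gibbs_chain(
            y, X, Z, pid, n_p, prior_prec,
            (cfg.warmup, cfg.samples), np.random.default_rng(ss))
        chains_beta.append(bdraws)
        chains_sigma.append(sdraws)
        chains_tau.append(tdraws)
    beta = np.stack(chains_beta)
    sigma = np.stack(chains_sigma)
    tau = np.stack(chains_tau)

    rhat = pd.Series({name: _split_rhat(beta[:, :, j])
                      for j, name in enumerate(TERM_NAMES)})
    post = HierarchicalPosterior(
        beta=beta, sigma=sigma, tau=tau, term_names=list(TERM_NAMES),
        outcome=outcome, prior_sd=prior_sd, rhat=rhat, config=cfg,
        n_rows=len(y), n_participants=n_p, n_dropped=n_dropped)
    if rhat.max() > cfg.rhat_threshold:
        msg = ("chains did not converge; split-R-hat table:\n"
               + rhat.sort_values(ascending=False).to_string())
        if on_nonconvergence == "raise":
            raise ConvergenceError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    return post


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hdi(samples, mass: float = 0.95):
    """Shortest contiguous interval holding ``mass`` of the draws.

    Sliding window over the sorted draws; with constant draws the interval
    has zero width.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("no draws")
    n_in = int(math.ceil(mass * n))
    if n_in >= n:
        return float(x[0]), float(x[-1])
    widths = x[n_in - 1 + np.arange(n - n_in + 1)] - x[: n - n_in + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_in - 1])


def savage_dickey_bf(samples, prior_sd: float, method: str = "normal") -> float:
    """Savage-Dickey BF10 for a contrast against the point null at zero.

    prior: normal(0, prior_sd). The posterior density at zero comes from a
    normal approximation to the draws (default, stable at extreme BFs) or a
    Gaussian KDE (method='kde').
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) posterior draws")
    if not prior_sd > 0:
        raise ValueError("prior_sd must be > 0")
    prior_at_0 = stats.norm.pdf(0.0, 0.0, prior_sd)
    if method == "normal":
        post_at_0 = stats.norm.pdf(0.0, x.mean(), sd)
    elif method == "kde":
        post_at_0 = float(stats.gaussian_kde(x)(0.0)[0])
        post_at_0 = max(post_at_0, 1e-300)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(prior_at_0 / max(post_at_0, 1e-300))


def classify_bf(bf10: float) -> str:
    """Evidence band for a BF10: strong/moderate for or against, or ambiguous.

    Bands: < 0.1 strong-against; [0.1, 0.3) moderate-against; [0.3, 3]
    ambiguous; (3, 10] moderate-for; > 10 strong-for.
    """
    if not bf10 > 0 or not math.isfinite(bf10):
        raise ValueError(f"bf10 must be positive and finite, got {bf10}")
    if bf10 < 0.1:
        return "strong-against"
    if bf10 < 0.3:
        return "moderate-against"
    if bf10 <= 3.0:
        return "ambiguous"
    if bf10 <= 10.0:
        return "moderate-for"
    return "strong-for"


def effect_estimate(draws, prior_sd: float, mass: float = 0.95,
                    method: str = "normal") -> EffectEstimate:
    lo, hi = hdi(draws, mass)
    bf = savage_dickey_bf(draws, prior_sd, method=method)
    return EffectEstimate(delta=float(np.mean(draws)), hdi_low=lo, hdi_high=hi,
                          bf10=bf, label=classify_bf(bf))


# standard contrasts ---------------------------------------------------------

def cue_effect_cells(task=None, age_group=None, paradigm=None):
    """Weighted cells for the retro-cue minus no-cue contrast, averaged over
    any unspecified factor; optionally restricted to one paradigm."""
    if task is not None:
        tasks = [task]
    elif paradigm is not None:
        tasks = [t for t in TASKS if task_family(t) == paradigm]
    else:
        tasks = list(TASKS)
    groups = [age_group] if age_group else list(AGE_GROUPS)
    w = 1.0 / (len(tasks) * len(groups))
    cells = []
    for t in tasks:
        for g in groups:
            cells += [(g, t, "retro_cue", w), (g, t, "no_cue", -w)]
    return cells


def age_difference_cells(task=None, on: str = "no_cue", paradigm=None):
    """Younger minus older, either on the no-cue baseline (on='no_cue') or on
    the retro-cue effect (on='cue_effect'); optionally restricted to one task
    or one paradigm."""
    if task is not None:
        tasks = [task]
    elif paradigm is not None:
        tasks = [t for t in TASKS if task_family(t) == paradigm]
    else:
        tasks = list(TASKS)
    w = 1.0 / len(tasks)
    cells = []
    for t in tasks:
        if on == "no_cue":
            cells += [("younger", t, "no_cue", w), ("older", t, "no_cue", -w)]
        elif on == "cue_effect":
            cells += [("younger", t, "retro_cue", w), ("younger", t, "no_cue", -w),
                      ("older", t, "retro_cue", -w), ("older", t, "no_cue", w)]
        else:
            raise ValueError(f"unknown target {on!r}")
    return cells


def moderator_cells(factor: str, on: str = "cue_effect"):
    """Difference in the cue effect between the levels of 'paradigm'
    (DE minus CD) or 'material' (color minus orientation)."""
    if factor == "paradigm":
        hi = [t for t in TASKS if task_family(t) == "de"]
        lo = [t for t in TASKS if task_family(t) == "cd"]
    elif factor == "material":
        hi = [t for t in TASKS if t.startswith("color")]
        lo = [t for t in TASKS if t.startswith("orientation")]
    else:
        raise ValueError(f"unknown factor {factor!r}")
    cells = []
    for sign, tasks in ((1.0, hi), (-1.0, lo)):
        w = sign / (len(tasks) * len(AGE_GROUPS))
        for t in tasks:
            for g in AGE_GROUPS:
                cells += [(g, t, "retro_cue", w), (g, t, "no_cue", -w)]
    return cells
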