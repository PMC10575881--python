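"""Model/Results front end for the group-level retro-cue analysis.

``RetroCueEffectsModel`` wraps the hierarchical mixed model of one diffusion
parameter; ``fit()`` returns an ``EffectsResults`` carrying the posterior
draws, from which cell means, retro-cue effects, age differences and their
Savage-Dickey Bayes factors are derived as linear contrasts of the fixed
effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AGE_GROUPS, TASKS, EffectEstimate
from . import inference as inf


class RetroCueEffectsModel:
    """Bayesian mixed model of one diffusion parameter across the cohort.

    Parameters
    ----------
    param_table : DataFrame
        Rectangular EZ output: one row per participant x task x condition
        with columns participant, age_group, task, condition and the outcome.
    outcome : {'nu', 'ter', 'a'}
    prior_sd : float
        SD of the normal(0, .) prior on non-intercept fixed effects.
    """

    def __init__(self, param_table: pd.DataFrame, outcome: str,
                 prior_sd: float = 0.5):
        if outcome not in inf.OUTCOMES:
            raise ValueError(f"outcome must be one of {inf.OUTCOMES}")
        self.param_table = param_table
        self.outcome = outcome
        self.prior_sd = prior_sd

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, **kw):
        return cls(df, outcome, **kw)

    def fit(self, cfg: inf.McmcConfig | None = None,
            on_nonconvergence: str = "raise") -> "EffectsResults":
        post = inf.fit_hierarchical_effects(
            self.param_table, self.outcome, cfg=cfg, prior_sd=self.prior_sd,
            on_nonconvergence=on_nonconvergence)
        return EffectsResults(self, post)


class EffectsResults:
    """Posterior summaries for one fitted outcome."""

    def __init__(self, model: RetroCueEffectsModel, posterior):
        self.model = model
        self.posterior = posterior
        self.outcome = posterior.outcome

    # -- draws ---------------------------------------------------------------
    def contrast_draws(self, cells) -> np.ndarray:
        return self.posterior.contrast_draws(inf.contrast_vector(cells))

    def cell_mean_draws(self, age_group: str, task: str, condition: str):
        return self.posterior.contrast_draws(
            inf.design_row(age_group, task, condition))

    # -- estimates -----------------------------------------------------------
    def contrast(self, cells, method: str = "normal") -> EffectEstimate:
        c = inf.contrast_vector(cells)
        draws = self.posterior.contrast_draws(c)
        prior = inf.implied_prior_sd(c, self.model.prior_sd)
        return inf.effect_estimate(draws, prior, method=method)

    def cue_effect(self, task=None, age_group=None, paradigm=None) -> EffectEstimate:
        """Retro-cue minus no-cue, averaged over unspecified factors."""
        return self.contrast(inf.cue_effect_cells(task, age_group, paradigm))

    def age_difference(self, task=None, on="no_cue", paradigm=None) -> EffectEstimate:
        """Younger minus older on a baseline or on the cue effect."""
        return self.contrast(inf.age_difference_cells(task, on=on, paradigm=paradigm))

    def moderation(self, factor: str) -> EffectEstimate:
        """Cue-effect difference between paradigms or materials."""
        return self.contrast(inf.moderator_cells(factor))

    def no_cue_mean(self, task: str, age_group: str):
        """Posterior mean and 95% HDI of a no-cue cell mean (no BF: the cell
        mean involves the intercept, whose prior is vague)."""
        draws = self.cell_mean_draws(age_group, task, "no_cue")
        lo, hi = inf.hdi(draws)
        return float(draws.mean()), lo, hi

    # -- tables --------------------------------------------------------------
    def effect_table(self) -> pd.DataFrame:
        """Per task x age group: no-cue mean with HDI, retro-cue effect with
        HDI and BF10, and the age-difference BFs (no-cue and cue-effect)."""
        rows = []
        for task in TASKS:
            for g in AGE_GROUPS:
                m, lo, hi = self.no_cue_mean(task, g)
                eff = self.cue_effect(task, g)
                rows.append({
                    "outcome": self.outcome, "task": task, "age_group": g,
                    "nocue_mean": m, "nocue_hdi_low": lo, "nocue_hdi_high": hi,
                    "effect_mean": eff.delta, "effect_hdi_low": eff.hdi_low,
                    "effect_hdi_high": eff.hdi_high, "effect_bf10": eff.bf10,
                    "effect_label": eff.label,
                })
        return pd.DataFrame(rows)

    def age_table(self) -> pd.DataFrame:
        rows = []
        for task in TASKS:
            for on in ("no_cue", "cue_effect"):
                est = self.age_difference(task, on=on)
                rows.append({"outcome": self.outcome, "task": task, "target": on,
                             "delta": est.delta, "hdi_low": est.hdi_low,
                             "hdi_high": est.hdi_high, "bf10": est.bf10,
                             "label": est.label})
        return pd.DataFrame(rows)

    def overall_table(self) -> pd.DataFrame:
        """Cohort-level contrasts: overall cue effect, its paradigm and
        material moderators, and overall age differences."""
        entries = {
            "cue_effect": self.cue_effect(),
            "cue_effect_by_paradigm": self.moderation("paradigm"),
            "cue_effect_by_material": self.moderation("material"),
            "age_diff_no_cue": self.age_difference(on="no_cue"),
            "age_diff_cue_effect": self.age_difference(on="cue_effect"),
        }
        return pd.DataFrame(
            [{"outcome": self.outcome, "contrast": k, "delta": v.delta,
              "hdi_low": v.hdi_low, "hdi_high": v.hdi_high, "bf10": v.bf10,
              "label": v.label} for k, v in entries.items()])

    def summary(self) -> str:
        post = self.posterior
        cfg = post.config
        lines = [
            f"Hierarchical retro-cue effects model — outcome: {self.outcome}",
            f"rows: {post.n_rows}  participants: {post.n_participants}"
            f"  dropped cells: {post.n_dropped}",
            f"chains: {cfg.chains}  warmup: {cfg.warmup}  draws/chain: {cfg.samples}"
            f"  max split-R-hat: {post.rhat.max():.4f}",
            "",
            "Cohort-level contrasts (posterior mean, 95% HDI, BF10):",
        ]
        for _, r in self.overall_table().iterrows():
            lines.append(
                f"  {r['contrast']:<24s} {r['delta']:+7.3f}"
                f"  [{r['hdi_low']:+.3f}, {r['hdi_high']:+.3f}]"
                f"  BF10={r['bf10']:.3g} ({r['label']})")
        lines.append("")
        lines.append("Per-task retro-cue effects:")
        for _, r in self.effect_table().iterrows():
            lines.append(
                f"  {r['task']:<15s} {r['age_group']:<8s}"
                f" no-cue {r['nocue_mean']:.3f} [{r['nocue_hdi_low']:.3f},"
                f" {r['nocue_hdi_high']:.3f}]"
                f"  effect {r['effect_mean']:+.3f} [{r['effect_hdi_low']:+.3f},"
                f" {r['effect_hdi_high']:+.3f}] BF10={r['effect_bf10']:.3g}")
        return "\n".join(lines)

    def plot_effects(self, ax=None):
        """Forest plot of the retro-cue effect per task and age group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        tab = self.effect_table()
        ypos = np.arange(len(tab))[::-1]
        for (_, r), y in zip(tab.iterrows(), ypos):
            color = "k" if r["age_group"] == "younger" else "grey"
            ax.errorbar(r["effect_mean"], y,
                        xerr=[[r["effect_mean"] - r["effect_hdi_low"]],
                              [r["effect_hdi_high"] - r["effect_mean"]]],
                        fmt="o", color=color, capsize=3)
        ax.axvline(0.0, color="0.6", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels([f"{r['task']} / {r['age_group']}" for _, r in tab.iterrows()])
        ax.set_xlabel(f"retro-cue effect on {self.outcome}")
        return ax
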