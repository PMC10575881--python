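"""HDI, Savage-Dickey, BF bands and the hierarchical model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import retrocue_ddm as r
from retrocue_ddm.inference import (ConvergenceError, McmcConfig,
                                    classify_bf, contrast_vector,
                                    cue_effect_cells, design_row, hdi,
                                    implied_prior_sd, savage_dickey_bf)
from retrocue_ddm.models import RetroCueEffectsModel


class TestHdi:
    def test_matches_brute_force_on_small_samples(self, rng):
        for _ in range(20):
            x = np.sort(rng.lognormal(0, 1, 20))
            n_in = int(np.ceil(0.95 * 20))
            widths = [x[i + n_in - 1] - x[i] for i in range(20 - n_in + 1)]
            i = int(np.argmin(widths))
            assert hdi(x, 0.95) == (x[i], x[i + n_in - 1])

    def test_standard_normal_quantiles(self, rng):
        lo, hi = hdi(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_draws_zero_width(self):
        assert hdi(np.full(100, 3.3)) == (3.3, 3.3)

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_mass(self, mass):
        with pytest.raises(ValueError):
            hdi(np.arange(10.0), mass)

    def test_width_shrinks_with_sample_information(self, rng):
        """Posterior HDI width scales like 1/sqrt(n) across cohort sizes."""
        widths = []
        for n in (40, 160):
            draws = rng.normal(0.3, 1.0 / np.sqrt(n), 5000)
            lo, hi = hdi(draws)
            widths.append(hi - lo)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.15)


class TestSavageDickey:
    def test_posterior_equal_prior_gives_unit_bf(self, rng):
        draws = rng.normal(0.0, 0.5, 200_000)
        assert savage_dickey_bf(draws, 0.5) == pytest.approx(1.0, rel=0.02)

    def test_prior_density_value(self):
        # the normal(0, 0.5) prior has density 0.797885 at zero
        assert stats.norm.pdf(0, 0, 0.5) == pytest.approx(0.7978845608)

    def test_conjugate_normal_oracle(self, rng):
        """Matches the closed-form marginal-likelihood ratio in the
        normal-normal model with known observation noise."""
        t, s, n = 0.5, 1.0, 50
        y = rng.normal(0.3, s, n)
        post_var = 1.0 / (1 / t**2 + n / s**2)
        post_mean = post_var * y.sum() / s**2
        exact = stats.norm.pdf(0, 0, t) / stats.norm.pdf(0, post_mean, np.sqrt(post_var))
        draws = rng.normal(post_mean, np.sqrt(post_var), 40_000)
        assert savage_dickey_bf(draws, t) == pytest.approx(exact, rel=0.05)
        # the KDE route carries bandwidth bias in the far tail; looser check
        assert savage_dickey_bf(draws, t, method="kde") == pytest.approx(exact, rel=0.2)

    def test_sign_flip_symmetry(self, rng):
        draws = rng.normal(0.4, 0.1, 10_000)
        assert savage_dickey_bf(-draws, 0.5) == pytest.approx(
            savage_dickey_bf(draws, 0.5))

    def test_degenerate_draws_rejected(self):
        with pytest.raises(ValueError):
            savage_dickey_bf(np.full(100, 1.0), 0.5)


class TestClassifyBf:
    @pytest.mark.parametrize("bf,label", [
        (0.05, "strong-against"), (0.2, "moderate-against"), (0.3, "ambiguous"),
        (1.5, "ambiguous"), (3.0, "ambiguous"), (5.0, "moderate-for"),
        (4.2e4, "strong-for")])
    def test_bands(self, bf, label):
        assert classify_bf(bf) == label

    @pytest.mark.parametrize("bf", [0.0, -1.0, np.inf])
    def test_invalid(self, bf):
        with pytest.raises(ValueError):
            classify_bf(bf)


class TestDesign:
    def test_cell_design_rows_are_full_rank(self):
        rows = np.stack([design_row(g, t, c)
                         for g in ("younger", "older")
                         for t in ("color_cd", "orientation_cd", "color_de",
                                   "orientation_de")
                         for c in ("no_cue", "retro_cue")])
        assert np.linalg.matrix_rank(rows) == 16

    def test_overall_cue_contrast_is_pure_main_effect(self):
        c = contrast_vector(cue_effect_cells())
        # averaging over tasks and groups leaves exactly the cue main effect
        nonzero = {i for i, v in enumerate(c) if abs(v) > 1e-12}
        assert len(nonzero) == 1
        assert implied_prior_sd(c) == pytest.approx(0.5)

    def test_intercept_contrast_rejected(self):
        with pytest.raises(ValueError):
            implied_prior_sd(design_row("younger", "color_cd", "no_cue"))


class TestMcmcConfig:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(chains=1)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(rhat_threshold=0.9)


@pytest.fixture(scope="module")
def fitted_nu():
    """Model fitted to a generator-truth parameter table (40/group)."""
    design = r.StudyDesign(tasks=r.DEFAULT_TASKS,
                           n_participants={"younger": 40, "older": 40}, seed=7)
    tab = r.build_param_table(design, rng=np.random.default_rng(11))
    cfg = McmcConfig(chains=4, warmup=300, samples=1000, seed=5)
    return RetroCueEffectsModel(tab, "nu").fit(cfg)


class TestHierarchicalFit:
    def test_recovers_generating_cue_effect(self, fitted_nu):
        # mean cue effect over the 8 generating cells is 0.545
        est = fitted_nu.cue_effect()
        assert est.delta == pytest.approx(0.545, abs=0.1)
        assert est.bf10 > 10

    def test_recovers_cell_level_effect(self, fitted_nu):
        est = fitted_nu.cue_effect("color_cd", "younger")
        assert est.delta == pytest.approx(0.75, abs=0.15)

    def test_convergence_diagnostics(self, fitted_nu):
        assert fitted_nu.posterior.rhat.max() < 1.05

    def test_rhat_agrees_with_arviz(self, fitted_nu):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az

            ours = fitted_nu.posterior.rhat
            theirs = az.rhat(az.convert_to_dataset(
                {"beta": fitted_nu.posterior.beta}))["beta"].values
        assert np.allclose(ours.to_numpy(), theirs, atol=0.02)

    def test_effect_table_shape(self, fitted_nu):
        tab = fitted_nu.effect_table()
        assert len(tab) == 8
        assert (tab["effect_hdi_low"] <= tab["effect_mean"]).all()
        assert (tab["effect_mean"] <= tab["effect_hdi_high"]).all()

    def test_summary_text(self, fitted_nu):
        txt = fitted_nu.summary()
        assert "cue_effect" in txt and "split-R-hat" in txt

    def test_plot_returns_axes(self, fitted_nu):
        import matplotlib

        matplotlib.use("Agg")
        ax = fitted_nu.plot_effects()
        assert ax.get_xlabel().endswith("nu")

    def test_same_seed_reproduces_posterior(self):
        design = r.StudyDesign(tasks=r.DEFAULT_TASKS,
                               n_participants={"younger": 10, "older": 10}, seed=3)
        tab = r.build_param_table(design, rng=np.random.default_rng(4))
        cfg = McmcConfig(chains=2, warmup=100, samples=200, seed=9)
        a = RetroCueEffectsModel(tab, "ter").fit(cfg, on_nonconvergence="warn")
        b = RetroCueEffectsModel(tab, "ter").fit(cfg, on_nonconvergence="warn")
        assert np.array_equal(a.posterior.beta, b.posterior.beta)

    def test_nonconvergence_reported(self):
        design = r.StudyDesign(tasks=r.DEFAULT_TASKS,
                               n_participants={"younger": 6, "older": 6}, seed=3)
        tab = r.build_param_table(design, rng=np.random.default_rng(4))
        cfg = McmcConfig(chains=2, warmup=0, samples=8, seed=1,
                         rhat_threshold=1.0000001)
        with pytest.raises(ConvergenceError):
            RetroCueEffectsModel(tab, "nu").fit(cfg)

    def test_null_cohort_keeps_bf_low(self):
        """With no condition effect injected, the cue-contrast BF10 stays
        below 1 (evidence for the null)."""
        null_means = {k: {p: (v[p][0], 0.0) for p in ("nu", "a", "ter")}
                      for k, v in r.GROUP_PARAM_MEANS.items()}
        design = r.StudyDesign(tasks=r.DEFAULT_TASKS,
                               n_participants={"younger": 30, "older": 30}, seed=0)
        hits = 0
        for rep in range(3):
            tab = r.build_param_table(
                design, group_means=null_means,
                rng=np.random.default_rng(100 + rep),
                cell_noise_sd={"nu": 0.1, "a": 0.1, "ter": 0.05})
            cfg = McmcConfig(chains=2, warmup=200, samples=600, seed=rep)
            res = RetroCueEffectsModel(tab, "nu").fit(cfg, on_nonconvergence="warn")
            est = res.cue_effect()
            hits += est.bf10 < 1.0 and est.hdi_low <= 0.0 <= est.hdi_high
        assert hits == 3

    def test_missing_cells_dropped_with_count(self, fitted_nu):
        tab = fitted_nu.model.param_table.copy()
        tab.loc[tab.index[:5], "nu"] = np.nan
        cfg = McmcConfig(chains=2, warmup=100, samples=300, seed=2)
        res = RetroCueEffectsModel(tab, "nu").fit(cfg, on_nonconvergence="warn")
        assert res.posterior.n_dropped == 5

    def test_unknown_outcome_rejected(self, fitted_nu):
        with pytest.raises(ValueError):
            RetroCueEffectsModel(fitted_nu.model.param_table, "zeta")
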