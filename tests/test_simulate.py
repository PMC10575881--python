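"""Simulator checks against closed-form first-passage results."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

import retrocue_ddm as r
from retrocue_ddm.datatypes import DMParams

N = 30_000  # per-case trial count for the distributional checks


@pytest.mark.parametrize("nu,a", [(0.5, 1.0), (1.0, 1.4), (1.5, 0.8)])
def test_choice_probability_matches_logistic(nu, a):
    """Empirical P(correct) agrees with 1/(1+exp(-nu*a/s^2)) within 3 MC SEs."""
    correct, _, _ = r.simulate_choice_trials(DMParams(nu, a, 0.2), N, rng=7)
    p = 1.0 / (1.0 + np.exp(-nu * a))
    se = np.sqrt(p * (1 - p) / N)
    assert abs(correct.mean() - p) < 3 * se


def test_zero_drift_choice_unbiased():
    correct, _, _ = r.simulate_choice_trials(DMParams(0.0, 1.2, 0.1), N, rng=8)
    assert abs(correct.mean() - 0.5) < 3 * np.sqrt(0.25 / N)


def test_choice_mean_decision_time_matches_closed_form():
    nu, a, ter = 1.0, 1.4, 0.3
    _, rt, _ = r.simulate_choice_trials(DMParams(nu, a, ter), N, rng=9)
    y = -nu * a
    mdt = (a / (2 * nu)) * (1 - np.exp(y)) / (1 + np.exp(y))
    assert abs(rt.mean() - ter - mdt) < 4 * rt.std() / np.sqrt(N)


@pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
def test_circular_hitting_angle_resultant_length(kappa):
    """Hitting angles are von Mises(target, a*nu/s^2): resultant length I1/I0."""
    resp, _, _ = r.simulate_circular_trials(
        DMParams(kappa, 1.0, 0.0), np.zeros(N), rng=int(10 * kappa))
    emp = np.abs(np.exp(1j * resp).mean())
    assert abs(emp - special.i1(kappa) / special.i0(kappa)) < 0.015


def test_zero_drift_uniform_hitting_angle():
    resp, _, _ = r.simulate_circular_trials(DMParams(0.0, 1.5, 0.0),
                                            np.zeros(N), rng=3)
    assert np.abs(np.exp(1j * resp).mean()) < 3.0 / np.sqrt(N)


def test_zero_drift_mean_exit_time():
    """Mean exit time of driftless diffusion from the disk center is a^2/(2s^2)."""
    a = 1.2
    _, rt, _ = r.simulate_circular_trials(DMParams(0.0, a, 0.0),
                                          np.zeros(N), rng=4)
    assert abs(rt.mean() / (a**2 / 2.0) - 1.0) < 0.02


def test_rt_never_below_nondecision_time():
    p = DMParams(1.0, 1.0, 0.77)
    _, rt_c, _ = r.simulate_choice_trials(p, 500, rng=1)
    _, rt_d, _ = r.simulate_circular_trials(p, np.zeros(500), rng=1)
    assert rt_c.min() >= 0.77 and rt_d.min() >= 0.77


def test_halving_dt_leaves_statistics_unchanged():
    """Discretisation convergence: dt and dt/2 agree within MC noise."""
    p = DMParams(1.0, 1.4, 0.2)
    n = 20_000
    c1, rt1, _ = r.simulate_choice_trials(p, n, dt=1e-3, rng=21)
    c2, rt2, _ = r.simulate_choice_trials(p, n, dt=5e-4, rng=22)
    se_p = np.sqrt(2 * 0.25 / n)
    se_t = np.sqrt(rt1.var() / n + rt2.var() / n)
    assert abs(c1.mean() - c2.mean()) < 3 * se_p
    assert abs(rt1.mean() - rt2.mean()) < 3 * se_t


def test_invalid_parameters_and_dt_rejected():
    with pytest.raises(ValueError):
        DMParams(1.0, -1.0, 0.1)
    with pytest.raises(ValueError):
        DMParams(np.inf, 1.0, 0.1)
    with pytest.raises(ValueError):
        r.simulate_choice_trials(DMParams(1.0, 1.0, 0.1), 10, dt=0.0)
    with pytest.raises(ValueError):
        r.simulate_circular_trials(DMParams(-0.5, 1.0, 0.1), [0.0])


def test_single_trial_wrappers():
    correct, rt = r.simulate_choice_trial(DMParams(1.0, 1.2, 0.3), rng=5)
    assert isinstance(correct, bool) and rt > 0.3
    ang, rt = r.simulate_circular_trial(DMParams(1.0, 1.2, 0.3), 1.0, rng=5)
    assert -np.pi <= ang < np.pi and rt > 0.3


class TestCohort:
    def test_counts_and_cue_split(self):
        design = r.StudyDesign(
            tasks=(r.TaskSpec("color_cd", n_trials=80, load={"younger": 6.0}),),
            n_participants={"younger": 10}, seed=5)
        cohort = r.generate_cohort(design)
        choice = cohort["choice"]
        assert len(choice) == 800
        per = choice.groupby(["participant", "condition"]).size()
        assert (per == 40).all()

    def test_fractional_load_mixture(self):
        design = r.StudyDesign(
            tasks=(r.TaskSpec("orientation_cd", n_trials=80,
                              load={"younger": 5.4, "older": 4.6}),),
            n_participants={"younger": 2, "older": 2}, seed=6)
        choice = r.generate_cohort(design)["choice"]
        for (_, grp), sub in choice.groupby(["participant", "age_group"]):
            counts = sub["load"].value_counts()
            if grp == "younger":
                assert counts[5] == 48 and counts[6] == 32
            else:
                assert counts[5] == 48 and counts[4] == 32

    def test_empty_participant_list(self):
        design = r.StudyDesign(tasks=r.DEFAULT_TASKS, n_participants={}, seed=1)
        cohort = r.generate_cohort(design)
        assert cohort["choice"].empty and cohort["circular"].empty

    def test_same_seed_bit_identical(self, small_design, small_cohort):
        again = r.generate_cohort(small_design)
        pd.testing.assert_frame_equal(small_cohort["choice"], again["choice"])
        pd.testing.assert_frame_equal(small_cohort["circular"], again["circular"])

    def test_missing_parameter_cell_raises(self):
        design = r.StudyDesign(
            tasks=(r.TaskSpec("color_cd", n_trials=8, load={"younger": 6.0}),),
            n_participants={"younger": 2}, seed=3)
        params = r.build_param_table(design).iloc[:-1]  # drop one cell
        with pytest.raises(KeyError):
            r.generate_cohort(design, params=params)

    def test_retro_cue_improves_speed_and_accuracy(self):
        """At the default group means, retro-cue trials are more accurate and
        faster than no-cue trials in both paradigms."""
        design = r.StudyDesign(
            tasks=(r.TaskSpec("color_cd", n_trials=40, load={"younger": 6.0}),
                   r.TaskSpec("color_de", n_trials=40, load={"younger": 5.8})),
            n_participants={"younger": 100}, seed=11)
        cohort = r.generate_cohort(design)
        cd = cohort["choice"].groupby("condition")
        assert (cd["correct"].mean()["retro_cue"] > cd["correct"].mean()["no_cue"])
        assert (cd["rt"].mean()["retro_cue"] < cd["rt"].mean()["no_cue"])
        de = cohort["circular"]
        vec = np.exp(1j * (de["response_angle"] - de["target_angle"]))
        # resultant length of report errors: higher = more accurate
        acc = vec.groupby(de["condition"]).agg(lambda v: np.abs(np.mean(v)))
        assert acc["retro_cue"] > acc["no_cue"]
        dert = de.groupby("condition")["rt"].mean()
        assert dert["retro_cue"] < dert["no_cue"]


def test_param_table_covers_design_and_clips(small_design):
    with pytest.warns(UserWarning):
        # tiny means force clipping
        bad_means = {k: {"nu": (0.01, 0.0), "a": (0.01, 0.0), "ter": (0.01, 0.0)}
                     for k in r.GROUP_PARAM_MEANS}
        tab = r.build_param_table(small_design, group_means=bad_means,
                                  rng=np.random.default_rng(0))
    assert (tab["a"] >= 0.05).all() and (tab["ter"] >= 0.0).all()
    tab = r.build_param_table(small_design, rng=np.random.default_rng(1))
    assert len(tab) == 16 * 4 * 2
    assert not tab.duplicated(["participant", "task", "condition"]).any()
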