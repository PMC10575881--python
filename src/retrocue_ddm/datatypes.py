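"""Core value types shared across the pipeline.

Angles are radians internally (wrapped to [-pi, pi)) and degrees in files.
Reaction times are seconds everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CD_TASKS = ("color_cd", "orientation_cd")
DE_TASKS = ("color_de", "orientation_de")
TASKS = CD_TASKS + DE_TASKS
AGE_GROUPS = ("younger", "older")
CONDITIONS = ("no_cue", "retro_cue")


def task_family(task: str) -> str:
    """Return 'cd' (two-choice change detection) or 'de' (delayed estimation)."""
    if task in CD_TASKS:
        return "cd"
    if task in DE_TASKS:
        return "de"
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def wrap_angle(theta):
    """Wrap angle(s) to the principal domain [-pi, pi)."""
    return (np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class DMParams:
    """Diffusion-model parameter triple plus the within-trial scaling.

    nu : drift rate (evidence/s). Signed for the two-choice model (positive
        drives the correct boundary); magnitude >= 0 for the circular model.
    a : boundary separation (two-choice) or boundary radius (circular), > 0.
    ter : nondecision time in seconds, >= 0.
    s : within-trial diffusion coefficient (evidence/sqrt(s)), > 0.
    """

    nu: float
    a: float
    ter: float
    s: float = 1.0

    def __post_init__(self):
        for name in ("nu", "a", "ter", "s"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"DMParams.{name} must be finite, got {v!r}")
        if self.a <= 0:
            raise ValueError(f"boundary a must be > 0, got {self.a}")
        if self.s <= 0:
            raise ValueError(f"scaling s must be > 0, got {self.s}")
        if self.ter < 0:
            raise ValueError(f"nondecision time ter must be >= 0, got {self.ter}")

    @property
    def kappa(self) -> float:
        """Von Mises concentration of the circular hitting angle, a*nu/s^2."""
        return self.a * self.nu / self.s**2


@dataclass(frozen=True)
class ChoiceSummary:
    """Moment statistics consumed by the two-choice EZ estimator."""

    pc: float          # proportion correct (edge-corrected upstream)
    mrt: float         # median RT of correct trials, s
    vrt: float         # sample variance of correct-trial RTs, s^2
    n: int             # trial count after trimming

    def __post_init__(self):
        if not 0.0 <= self.pc <= 1.0:
            raise ValueError(f"pc must lie in [0, 1], got {self.pc}")
        if self.vrt < 0:
            raise ValueError(f"vrt must be >= 0, got {self.vrt}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class CircSummary:
    """Moment statistics consumed by the circular EZ estimator.

    cv is the circular variance of report errors (1 - mean resultant length),
    mad the mean absolute circular deviation in radians, vrt a robust RT
    variance computed from the normalized interquartile range.
    """

    cv: float
    mad: float
    mrt: float
    vrt: float
    n: int
    vrt_reliable: bool = True   # False when n < 4

    def __post_init__(self):
        if not 0.0 <= self.cv <= 1.0:
            raise ValueError(f"cv must lie in [0, 1], got {self.cv}")
        if not 0.0 <= self.mad <= math.pi:
            raise ValueError(f"mad must lie in [0, pi], got {self.mad}")
        if self.vrt < 0:
            raise ValueError(f"vrt must be >= 0, got {self.vrt}")


@dataclass(frozen=True)
class TaskSpec:
    """One task of the cohort design."""

    name: str                      # e.g. 'color_cd'
    n_trials: int                  # test trials per participant
    cue_proportion: float = 0.5    # fraction of retro-cue trials
    load: dict = field(default_factory=dict)   # age_group -> mean load (may be fractional)

    def __post_init__(self):
        task_family(self.name)
        if not 0.0 < self.cue_proportion < 1.0:
            raise ValueError("cue_proportion must lie in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class StudyDesign:
    """Tasks x age groups x trial counts driving the synthetic cohort."""

    tasks: tuple
    n_participants: dict           # age_group -> count
    seed: int = 0

    def __post_init__(self):
        for g in self.n_participants:
            if g not in AGE_GROUPS:
                raise ValueError(f"unknown age group {g!r}")

    @property
    def participants(self):
        """(participant_id, age_group) pairs, ids unique across groups."""
        out = []
        pid = 0
        for g in AGE_GROUPS:
            for _ in range(self.n_participants.get(g, 0)):
                out.append((f"p{pid:04d}", g))
                pid += 1
        return out


@dataclass(frozen=True)
class EffectEstimate:
    """Posterior summary of one contrast: mean, 95% HDI, Savage-Dickey BF."""

    delta: float
    hdi_low: float
    hdi_high: float
    bf10: float
    label: str

    def __post_init__(self):
        if not self.hdi_low <= self.delta <= self.hdi_high:
            raise ValueError("posterior mean must lie inside its HDI")
        if not self.bf10 > 0:
            raise ValueError("bf10 must be positive")
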