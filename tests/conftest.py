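import numpy as np
import pandas as pd
import pytest

import retrocue_ddm as r
from retrocue_ddm.io import combined_trials


@pytest.fixture(scope="session")
def small_design():
    return r.StudyDesign(tasks=r.DEFAULT_TASKS,
                         n_participants={"younger": 8, "older": 8}, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """One 16-participant cohort of all four tasks, shared across tests."""
    return r.generate_cohort(small_design)


@pytest.fixture(scope="session")
def small_trials(small_cohort):
    return combined_trials(small_cohort["choice"], small_cohort["circular"])


@pytest.fixture(scope="session")
def small_params(small_trials):
    from retrocue_ddm.ez_cdm import estimate_circular_params
    from retrocue_ddm.ez_dm import estimate_choice_params
    from retrocue_ddm.preprocess import summarize_trials

    summaries, _ = summarize_trials(small_trials)
    return pd.concat(
        [estimate_choice_params(summaries[summaries["family"] == "cd"]),
         estimate_circular_params(summaries[summaries["family"] == "de"])],
        ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
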