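import numpy as np
import pandas as pd
import pytest

from controlshift import design
from controlshift.diffusion import DDMShiftParams, simulate_condition


@pytest.fixture(scope="session")
def exp1():
    return design.experiment_config(1)


@pytest.fixture(scope="session")
def exp2():
    return design.experiment_config(2)


@pytest.fixture(scope="session")
def small_cohort():
    """Small DDM cohort (3 subjects per group, 2 blocks x 40 trials)."""
    config = design.experiment_config(1, n_blocks=2, trials_per_block=40)
    spec = design.CohortSpec(n_subjects_per_group=3, model="ddm", seed=11)
    trials, true_params = design.generate_cohort(spec, config)
    return trials, true_params, config


def simulate_subject_table(params, n_per_condition, seed, subject_id="s001",
                           group="reward_congruent", dt=0.001):
    """Flat trial table for one subject generated directly from a simulator."""
    rng = np.random.default_rng(seed)
    frames = []
    for congruency in ("congruent", "incongruent"):
        res = simulate_condition(params, congruency, n_per_condition, rng, dt=dt)
        frames.append(pd.DataFrame({
            "subject_id": subject_id, "group": group, "block": 1,
            "trial": np.arange(len(res.rt)) + 1,
            "stimulus_id": [f"x{congruency[:1]}{i}" for i in range(len(res.rt))],
            "task": "size", "congruency": congruency, "transition": "repeat",
            "scheduled_high_reward": False,
            "rt_ms": np.where(res.censored, np.nan, res.rt * 1000.0),
            "accuracy": np.where(res.censored, np.nan,
                                 (res.response == 1).astype(float)),
            "reward": 0.0,
        }))
    return pd.concat(frames, ignore_index=True)
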