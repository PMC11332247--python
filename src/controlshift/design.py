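"""Trial-sequence and reward-schedule generation for the three task-switching experiments.

Designs cross task (size/animacy) with task-rule congruency within blocks of
unique stimuli; correct responses are rewarded probabilistically with a high
or low reward depending on the group's rewarded congruency condition.
Behaviour for synthetic cohorts is produced by the diffusion simulators in
:mod:`controlshift.diffusion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diffusion
from .diffusion import (CONGRUENT, INCONGRUENT, DDMShiftParams, DMCShiftParams,
                        simulate_condition)
from .trialtable import COLUMNS, validate_trials

GROUP_REWARD_CONGRUENT = "reward_congruent"
GROUP_REWARD_INCONGRUENT = "reward_incongruent"
GROUPS = (GROUP_REWARD_CONGRUENT, GROUP_REWARD_INCONGRUENT)

TASKS = ("size", "animacy")
MODELS = ("ddm", "dmc", "ddm_shift", "dmc_shift")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design constants of one experiment."""

    experiment_id: int
    n_blocks: int = 4
    trials_per_block: int = 80
    high_reward_prob_rewarded_condition: float = 0.90
    high_reward_prob_other_condition: float = 0.10
    response_deadline_ms: float = 3000.0
    cue_precedes_target: bool = False
    high_reward: float = 5.0
    low_reward: float = 1.0
    iti_ms: float = 1500.0
    repetition_half: bool = False

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3):
            raise ValueError("experiment_id must be 1, 2 or 3")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even to balance congruency")
        for p in (self.high_reward_prob_rewarded_condition,
                  self.high_reward_prob_other_condition):
            if not 0.0 <= p <= 1.0:
                raise ValueError("reward probabilities must lie in [0, 1]")
        if (self.high_reward_prob_rewarded_condition
                <= self.high_reward_prob_other_condition):
            raise ValueError("rewarded-condition probability must exceed the other condition")
        if self.response_deadline_ms <= 0:
            raise ValueError("response deadline must be > 0")
        if self.repetition_half and self.n_blocks % 2:
            raise ValueError("a repetition-half design needs an even block count")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def unique_blocks(self) -> int:
        """Blocks populated with unique stimuli (first half when stimuli repeat)."""
        return self.n_blocks // 2 if self.repetition_half else self.n_blocks


def experiment_config(experiment_id: int, **overrides) -> ExperimentConfig:
    """Canonical configuration of Experiments 1-3."""
    base = {
        1: dict(n_blocks=4, high_reward_prob_rewarded_condition=0.90,
                high_reward_prob_other_condition=0.10, high_reward=5.0,
                low_reward=1.0),
        2: dict(n_blocks=8, high_reward_prob_rewarded_condition=0.50,
                high_reward_prob_other_condition=0.00, high_reward=10.0,
                low_reward=1.0, repetition_half=True),
        3: dict(n_blocks=4, high_reward_prob_rewarded_condition=0.90,
                high_reward_prob_other_condition=0.10, high_reward=5.0,
                low_reward=1.0, cue_precedes_target=True),
    }
    if experiment_id not in base:
        raise ValueError("experiment_id must be 1, 2 or 3")
    kwargs = dict(base[experiment_id])
    kwargs.update(overrides)
    return ExperimentConfig(experiment_id=experiment_id, **kwargs)


def high_reward_prob(config: ExperimentConfig, group: str, congruency: str) -> float:
    """Probability that a correct trial of this condition is scheduled the high reward."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rewarded = (congruency == INCONGRUENT) == (group == GROUP_REWARD_INCONGRUENT)
    return (config.high_reward_prob_rewarded_condition if rewarded
            else config.high_reward_prob_other_condition)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _block_cells(trials_per_block: int, rng: np.random.Generator):
    """Balanced (task, congruency) labels for one block.

    Congruency is split exactly in half; within each congruency the two tasks
    are balanced to the nearest integer (the odd one out assigned at random).
    """
    half = trials_per_block // 2
    cells = []
    for congruency in (CONGRUENT, INCONGRUENT):
        n_size = half // 2
        n_extra = half % 2
        counts = {"size": n_size, "animacy": n_size}
        if n_extra:
            counts[TASKS[rng.integers(2)]] += 1
        for task, cnt in counts.items():
            cells.extend([(task, congruency)] * cnt)
    return cells


def build_design(config: ExperimentConfig, group: str, seed,
                 subject_id: str = "s001") -> pd.DataFrame:
    """Build one subject's trial sequence (design factors only, no behaviour).

    Produces the unique-stimulus portion of the experiment
    (``config.unique_blocks`` blocks); for a repetition design the second
    half is appended by :func:`build_repetition_half` once first-half
    rewards are known.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    rows = []
    stim_counter = 0
    for block in range(1, config.unique_blocks + 1):
        cells = _block_cells(config.trials_per_block, rng)
        order = rng.permutation(len(cells))
        prev_task = None
        for trial_idx, j in enumerate(order, start=1):
            task, congruency = cells[j]
            stim_counter += 1
            transition = None if prev_task is None else \
                ("repeat" if task == prev_task else "switch")
            prev_task = task
            p_high = high_reward_prob(config, group, congruency)
            rows.append({
                "subject_id": subject_id,
                "group": group,
                "block": block,
                "trial": trial_idx,
                "stimulus_id": f"w{stim_counter:04d}",
                "task": task,
                "congruency": congruency,
                "transition": transition,
                "scheduled_high_reward": bool(rng.random() < p_high),
                "rt_ms": np.nan,
                "accuracy": np.nan,
                "reward": np.nan,
            })
    return validate_trials(pd.DataFrame(rows, columns=COLUMNS))


def build_repetition_half(first_half: pd.DataFrame, config: ExperimentConfig,
                          seed) -> pd.DataFrame:
    """Second experiment half in which every first-half stimulus repeats once.

    Of the rewarded-condition stimuli that actually received the high reward
    in the first half, one third (floored; the remainder resolved by a
    seeded Bernoulli draw) is scheduled to be high-rewarded again; all other
    second-half trials are scheduled the low reward.  Every row carries a
    ``previously_high_rewarded`` tag.
    """
    first_half = validate_trials(first_half)
    if first_half["reward"].isna().all() or first_half["accuracy"].isna().all():
        raise ValueError("first half must carry delivered rewards (behaviour present)")
    if first_half["subject_id"].nunique() != 1:
        raise ValueError("build_repetition_half operates on one subject at a time")
    rng = np.random.default_rng(seed)
    subject_id = first_half["subject_id"].iloc[0]
    group = first_half["group"].iloc[0]
    rewarded_congruency = INCONGRUENT if group == GROUP_REWARD_INCONGRUENT else CONGRUENT

    got_high = first_half["reward"] == config.high_reward
    prev_high_ids = set(first_half.loc[got_high, "stimulus_id"])
    cond_high = first_half.loc[got_high & (first_half["congruency"] == rewarded_congruency),
                               "stimulus_id"].tolist()
    k = len(cond_high)
    n_again = k // 3
    if (k % 3) and rng.random() < (k % 3) / 3.0:
        n_again += 1
    again = set(rng.choice(cond_high, size=n_again, replace=False)) if n_again else set()

    stim = first_half[["stimulus_id", "congruency"]].drop_duplicates("stimulus_id")
    order = rng.permutation(len(stim))
    stim = stim.iloc[order].reset_index(drop=True)

    first_block = int(first_half["block"].max())
    rows = []
    prev_task = None
    for i, rec in stim.iterrows():
        block = first_block + 1 + i // config.trials_per_block
        trial_idx = i % config.trials_per_block + 1
        if trial_idx == 1:
            prev_task = None
        task = TASKS[rng.integers(2)]  # same or other task, at random
        transition = None if prev_task is None else \
            ("repeat" if task == prev_task else "switch")
        prev_task = task
        rows.append({
            "subject_id": subject_id,
            "group": group,
            "block": block,
            "trial": trial_idx,
            "stimulus_id": rec["stimulus_id"],
            "task": task,
            "congruency": rec["congruency"],
            "transition": transition,
            "scheduled_high_reward": rec["stimulus_id"] in again,
            "rt_ms": np.nan,
            "accuracy": np.nan,
            "reward": np.nan,
            "previously_high_rewarded": rec["stimulus_id"] in prev_high_ids,
        })
    return validate_trials(pd.DataFrame(rows, columns=COLUMNS + ["previously_high_rewarded"]))


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: population means/SDs used to draw per-subject generating parameters
DEFAULT_POPULATION = {
    "ddm": {"a": (0.15, 0.02), "v_congruent": (0.30, 0.05),
            "v_incongruent": (0.20, 0.05), "t0_mean": (0.30, 0.03),
            "t0_sd": (0.03, 0.0)},
    "dmc": {"b": (75.0, 8.0), "mu_c": (0.5, 0.05), "zeta": (20.0, 3.0),
            "t_peak": (0.04, 0.005), "t0_mean": (0.30, 0.03), "t0_sd": (0.03, 0.0)},
}
DEFAULT_POPULATION["ddm_shift"] = {
    **DEFAULT_POPULATION["ddm"],
    "shift_delta_congruent": (0.04, 0.01),
    "shift_delta_incongruent": (0.01, 0.01),
    "shift_time_mean": (0.20, 0.05),
    "shift_time_sd": (0.05, 0.0),
}
DEFAULT_POPULATION["dmc_shift"] = {
    **DEFAULT_POPULATION["dmc"],
    "shift_delta_congruent": (20.0, 5.0),
    "shift_delta_incongruent": (8.0, 5.0),
    "shift_time_mean": (0.20, 0.05),
    "shift_time_sd": (0.05, 0.0),
}

# hard ranges a drawn parameter is clipped into so every draw is valid
_PARAM_CLIPS = {
    "a": (0.02, 1.0), "z_rel": (0.05, 0.95), "v_congruent": (0.0, 2.0),
    "v_incongruent": (0.0, 2.0), "b": (10.0, 300.0), "mu_c": (0.05, 2.0),
    "zeta": (0.0, 100.0), "t_peak": (0.005, 0.5), "t0_mean": (0.05, 1.0),
    "t0_sd": (0.0, 0.2), "shift_time_mean": (0.0, 1.5), "shift_time_sd": (0.0, 0.3),
}


@dataclass(frozen=True)
class CohortSpec:
    """How to draw a synthetic cohort of subjects."""

    n_subjects_per_group: int
    model: str = "dmc_shift"
    seed: int = 0
    param_population: dict | None = None
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    def population(self) -> dict:
        return dict(self.param_population or DEFAULT_POPULATION[self.model])


def _draw_subject_params(model: str, population: dict, rng: np.random.Generator):
    values = {}
    for name, (mean, sd) in population.items():
        x = mean if sd == 0 else rng.normal(mean, sd)
        lo, hi = _PARAM_CLIPS.get(name, (-np.inf, np.inf))
        values[name] = float(np.clip(x, lo, hi))
    cls = DDMShiftParams if model.startswith("ddm") else DMCShiftParams
    # boundary-shift deltas may be negative but must not close the boundary
    base = values.get("a", values.get("b", 1.0))
    for key in ("shift_delta_congruent", "shift_delta_incongruent"):
        if key in values:
            values[key] = float(max(values[key], -0.9 * base))
    return cls(**values)


def generate_cohort(spec: CohortSpec, config: ExperimentConfig):
    """Simulate a full cohort: designs plus model-generated behaviour.

    Returns ``(trials, true_params)`` where ``true_params`` maps each
    subject id to its generating parameter object (for recovery studies).
    Trials whose simulated first passage misses the deadline are recorded as
    null responses (missing rt and accuracy, zero reward).
    """
    root = np.random.SeedSequence(spec.seed)
    population = spec.population()
    deadline = config.response_deadline_ms / 1000.0
    tables = []
    true_params = {}
    subj_counter = 0
    for group in GROUPS:
        for _ in range(spec.n_subjects_per_group):
            subj_counter += 1
            sid = f"s{subj_counter:03d}"
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            params = _draw_subject_params(spec.model, population, rng)
            true_params[sid] = params
            table = build_design(config, group, rng, subject_id=sid)
            for congruency in (CONGRUENT, INCONGRUENT):
                mask = (table["congruency"] == congruency).to_numpy()
                res = simulate_condition(params, congruency, int(mask.sum()), rng,
                                         dt=spec.dt, deadline=deadline)
                rt_ms = np.where(res.censored, np.nan, res.rt * 1000.0)
                acc = np.where(res.censored, np.nan,
                               (res.response == 1).astype(float))
                table.loc[mask, "rt_ms"] = rt_ms
                table.loc[mask, "accuracy"] = acc
            correct = table["accuracy"] == 1
            table["reward"] = np.where(
                correct & table["scheduled_high_reward"], config.high_reward,
                np.where(correct, config.low_reward, 0.0))
            tables.append(table)
    trials = pd.concat(tables, ignore_index=True)
    return trials, true_params
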