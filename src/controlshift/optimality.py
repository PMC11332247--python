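"""Reward-rate optimality sweep over boundary-shift x drift-rate combinations.

For each cell of a 16 x 16 grid, trials of one congruency condition are
simulated from the standard DDM with a boundary shift, rewards are delivered
according to the group's probabilistic schedule, and each trial's reward is
discounted by its reaction time plus the inter-trial interval.  Error and
censored trials earn zero.  The sweep is restricted to the DDM-with-shift
model, which carries separate drift rates per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import GROUPS, ExperimentConfig, high_reward_prob
from .diffusion import CONGRUENCIES, CONGRUENT, DDMShiftParams, simulate_condition


def default_shift_values() -> np.ndarray:
    """Boundary-shift grid: -0.05 to 0.1 in 16 steps of 0.01."""
    return np.round(np.linspace(-0.05, 0.10, 16), 10)


def default_drift_values() -> np.ndarray:
    """Drift-rate grid: 0 to 0.5 in 16 equal steps (~0.033)."""
    return np.linspace(0.0, 0.5, 16)


def discounted_reward(reward, rt, iti):
    """Reward divided by (reaction time + inter-trial interval), both seconds."""
    rt_arr = np.asarray(rt, dtype=float)
    if np.any(rt_arr <= 0):
        raise ValueError("rt must be > 0")
    if np.any(np.asarray(iti) < 0):
        raise ValueError("iti must be >= 0")
    out = np.asarray(reward, dtype=float) / (rt_arr + iti)
    if np.ndim(reward) == 0 and np.ndim(rt) == 0:
        return float(out)
    return out


@dataclass
class OptimalityGrid:
    shift_values: np.ndarray
    drift_values: np.ndarray
    #: (group, congruency) -> matrix of shape (n_shift, n_drift)
    mean_discounted_reward: dict
    n_trials_per_cell: int
    base_params: DDMShiftParams
    iti_s: float
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.shift_values) * len(self.drift_values)


def _cell_params(base: DDMShiftParams, congruency: str, shift: float,
                 drift: float) -> DDMShiftParams:
    if congruency == CONGRUENT:
        return replace(base, v_congruent=drift, shift_delta_congruent=shift)
    return replace(base, v_incongruent=drift, shift_delta_incongruent=shift)


def sweep_grid(base_params: DDMShiftParams, config: ExperimentConfig,
               shift_values=None, drift_values=None, n_trials: int = 2000,
               seed: int = 0, dt: float = 0.001,
               groups=GROUPS, congruencies=CONGRUENCIES) -> OptimalityGrid:
    """Mean discounted reward over the shift x drift grid per condition and group.

    All parameters except the swept condition's drift and boundary shift are
    held at ``base_params`` ("average estimates").  Deterministic given
    ``seed``; cells use independent spawned substreams so grid shape does
    not perturb individual cells.
    """
    shift_values = default_shift_values() if shift_values is None else np.asarray(shift_values, float)
    drift_values = default_drift_values() if drift_values is None else np.asarray(drift_values, float)
    if shift_values.size == 0 or drift_values.size == 0:
        raise ValueError("grids must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    deadline = config.response_deadline_ms / 1000.0
    iti_s = config.iti_ms / 1000.0
    root = np.random.SeedSequence(seed)
    grids = {}
    for group in groups:
        for congruency in congruencies:
            p_high = high_reward_prob(config, group, congruency)
            mat = np.empty((shift_values.size, drift_values.size))
            for i, shift in enumerate(shift_values):
                for j, drift in enumerate(drift_values):
                    rng = np.random.default_rng(root.spawn(1)[0])
                    params = _cell_params(base_params, congruency,
                                          float(shift), float(drift))
                    sim = simulate_condition(params, congruency, n_trials, rng,
                                             dt=dt, deadline=deadline)
                    correct = sim.valid & (sim.response == 1)
                    reward = np.zeros(n_trials)
                    high = rng.random(n_trials) < p_high
                    reward[correct] = np.where(high[correct], config.high_reward,
                                               config.low_reward)
                    rate = np.zeros(n_trials)
                    rate[correct] = discounted_reward(reward[correct],
                                                      sim.rt[correct], iti_s)
                    mat[i, j] = rate.mean()
            grids[(group, congruency)] = mat
    return OptimalityGrid(shift_values=shift_values, drift_values=drift_values,
                          mean_discounted_reward=grids,
                          n_trials_per_cell=n_trials, base_params=base_params,
                          iti_s=iti_s, seed=seed)


def write_grid(grid: OptimalityGrid, out_dir) -> list:
    """Write each condition's matrix as TSV plus a JSON metadata sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (group, congruency), mat in grid.mean_discounted_reward.items():
        path = out_dir / f"reward_rate_{group}_{congruency}.tsv"
        np.savetxt(path, mat, delimiter="\t")
        written.append(path)
    meta = {
        "shift_values": grid.shift_values.tolist(),
        "drift_values": grid.drift_values.tolist(),
        "n_trials_per_cell": grid.n_trials_per_cell,
        "iti_s": grid.iti_s,
        "seed": grid.seed,
        "base_params": asdict(grid.base_params),
        "matrix_layout": "rows = shift values, columns = drift values",
    }
    meta_path = out_dir / "reward_rate_meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    written.append(meta_path)
    return written
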