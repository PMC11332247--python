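# controlshift

Simulation and diffusion-model analysis of task-switching experiments in
which correct responses are rewarded contingent on task-rule congruency.
The package provides an end-to-end pipeline:

1. **design** — trial sequences and probabilistic reward schedules for three
   experiment variants (4 blocks x 80 unique-stimulus trials; 90/10 or 50/0
   high-reward probabilities for the rewarded vs. other congruency
   condition; an optional second half in which every stimulus repeats and
   one third of the previously high-rewarded stimuli is re-rewarded), plus
   synthetic cohorts whose behaviour is generated from the diffusion models
   below.
2. **diffusion** — first-passage simulators for a standard drift diffusion
   model (DDM, separate drift rates per congruency) and a diffusion model of
   conflict (DMC, gamma-shaped automatic activation producing fast errors),
   each optionally extended with a congruency-dependent within-trial
   boundary shift at a noisy shift time. Trial-varying non-decision time,
   Euler–Maruyama integration with a numba kernel, 3000 ms response
   deadline with censoring.
3. **preprocessing** — subject exclusions (accuracy at or below 60% per
   task, inattentive runs) and trial filters for the accuracy stream
   (missing responses, trials after a null or error) and the RT stream
   (additionally errors, RT < 200 ms, within-subject 1.5-IQR Tukey fences),
   plus per-subject congruency effects.
4. **fitting** — per-subject parameter estimation for the four model
   variants (ddm, dmc, ddm_shift, dmc_shift) by minimizing the two-sample
   Kolmogorov–Smirnov distance between observed and simulated signed RT
   distributions (errors negated, so one CDF encodes accuracy and both RT
   distributions), using differential evolution with common random numbers;
   goodness of fit via observed-vs-predicted quantile-mean and accuracy
   correlations.
5. **caf** — conditional accuracy functions (accuracy per RT quintile per
   congruency and group, edges pooled across subjects within group).
6. **group_stats** — group comparisons of congruency difference scores:
   pooled or Welch t-tests (Levene-based auto rule), Cohen's d with a
   noncentral-t confidence interval, all also computable from printed
   summary statistics.
7. **optimality** — reward-rate simulation over a 16 x 16 boundary-shift
   (−0.05 to 0.1) by drift-rate (0 to 0.5) grid; each cell's reward is
   discounted by reaction time plus the inter-trial interval.

## Command-line interface

```bash
controlshift simulate --experiment 1 --n-subjects 10 --model dmc_shift \
    --seed 1 --out trials.tsv
controlshift preprocess --in trials.tsv --stream rt --out trials_rt.tsv \
    --report exclusions.json
controlshift fit --in trials.tsv --model ddm_shift --seed 1 --profile ci \
    --out params.tsv
controlshift caf --in trials.tsv --out caf.tsv --plot caf.png
controlshift stats --params params.tsv --parameter shift_delta --out stats.json
controlshift optimality --experiment 1 --n-trials 2000 --seed 1 --out grids/
controlshift run --config run.json      # multi-stage pipeline with manifest
```

A pipeline config is a JSON document, e.g.

```json
{
  "seed": 1,
  "out_dir": "runs/demo",
  "profile": "ci",
  "simulate": {"experiment": 1, "n_subjects_per_group": 5, "model": "ddm_shift"},
  "preprocess": true,
  "fit": {"model": "ddm_shift"},
  "caf": true,
  "stats": {"parameter": "shift_delta"}
}
```

Trial tables are tab-separated text with a fixed column order
(`subject_id, group, block, trial, stimulus_id, task, congruency,
transition, scheduled_high_reward, rt_ms, accuracy, reward`); missing
values are empty fields.

## Conventions worth knowing

- DDM parameters use the classic sigma = 0.1 scaling with time in seconds;
  DMC parameters use the conflict-model convention (sigma = 4, drift in
  evidence units per millisecond) but all time-valued fields are seconds.
- Boundary shifts are step changes applied symmetrically (the DDM changes
  the boundary separation about the start point, the DMC moves both
  bounds), at a per-trial zero-truncated normal shift time measured from
  accumulation onset.
- Default fitting bounds are literature-based defaults, configurable via
  `--bounds`/function arguments.
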