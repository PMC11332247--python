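"""Subject- and trial-level exclusion rules plus descriptive congruency effects.

Two analysis streams are produced from a raw trial table:

* ``accuracy`` stream: missing (null) responses and trials immediately
  following a null response or an error are removed;
* ``rt`` stream: additionally removes error trials, responses faster than
  200 ms, and within-subject Tukey-fence outliers (1.5 IQR beyond the
  quartiles, quartiles by linear interpolation, computed once on the
  surviving trials and not iterated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trialtable import order_within_subject, validate_trials

STREAMS = ("accuracy", "rt")

FAST_RT_FLOOR_MS = 200.0


@dataclass
class ExclusionReport:
    """Bookkeeping of what was removed and why."""

    subjects_excluded: list = field(default_factory=list)  # (subject_id, reason)
    trials_removed: dict = field(default_factory=dict)     # reason -> count
    n_input: int = 0
    n_output: int = 0
    stream: str | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def exclude_subjects(trials: pd.DataFrame, accuracy_floor: float = 0.60,
                     inattentive_run: int = 10):
    """Remove whole subjects: at-or-below-chance accuracy in either task, or
    runs of >= ``inattentive_run`` consecutive null/sub-200 ms responses."""
    if not 0.0 < accuracy_floor < 1.0:
        raise ValueError("accuracy_floor must lie in (0, 1)")
    trials = validate_trials(trials)
    if trials.empty or trials["accuracy"].isna().all():
        raise ValueError("trial table contains no scored trials")

    excluded = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        per_task = sub.dropna(subset=["accuracy"]).groupby("task")["accuracy"].mean()
        if len(per_task) and per_task.min() <= accuracy_floor:
            excluded.append((sid, "low_accuracy"))
            continue
        ordered = order_within_subject(sub)
        bad = ordered["rt_ms"].isna() | (ordered["rt_ms"] < FAST_RT_FLOOR_MS)
        run, longest = 0, 0
        for flag in bad.to_numpy():
            run = run + 1 if flag else 0
            longest = max(longest, run)
        if longest >= inattentive_run:
            excluded.append((sid, "inattentive"))

    bad_ids = {sid for sid, _ in excluded}
    kept = trials[~trials["subject_id"].isin(bad_ids)].reset_index(drop=True)
    report = ExclusionReport(subjects_excluded=excluded,
                             n_input=len(trials), n_output=len(kept))
    return kept, report


def _tukey_fences(rts: np.ndarray):
    # linear-interpolation quartiles (numpy default, the "type 7" convention)
    q1, q3 = np.percentile(rts, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def filter_trials(trials: pd.DataFrame, stream: str):
    """Apply trial-level exclusions for one analysis stream.

    Removal order within subject: missing/post-null/post-error, then (rt
    stream only) errors, the 200 ms floor, and finally Tukey IQR fences
    computed per subject on the trials still standing.
    """
    if stream not in STREAMS:
        raise ValueError(f"unknown stream {stream!r}; expected one of {STREAMS}")
    trials = order_within_subject(validate_trials(trials))
    counts = {"missing": 0, "post_null": 0, "post_error": 0,
              "error": 0, "fast_rt": 0, "iqr_high": 0, "iqr_low": 0}

    kept_parts = []
    for (sid, block), sub in trials.groupby(["subject_id", "block"], sort=False):
        missing = sub["rt_ms"].isna() | sub["accuracy"].isna()
        # post-event flags are anchored on the original trial numbering, so a
        # trial whose predecessor was already removed is not re-flagged when
        # an already-filtered table is filtered again (idempotence)
        trial_no = sub["trial"].to_numpy()
        missing_by_trial = dict(zip(trial_no, missing.to_numpy()))
        error_by_trial = dict(zip(trial_no, (sub["accuracy"] == 0).to_numpy()))
        prev_missing = pd.Series(
            [missing_by_trial.get(t - 1, False) for t in trial_no], index=sub.index)
        prev_error = pd.Series(
            [error_by_trial.get(t - 1, False) for t in trial_no], index=sub.index)
        drop = missing.copy()
        counts["missing"] += int(missing.sum())
        post_null = prev_missing & ~drop
        counts["post_null"] += int(post_null.sum())
        drop |= prev_missing
        post_error = prev_error & ~drop
        counts["post_error"] += int(post_error.sum())
        drop |= prev_error
        sub = sub[~drop]
        if stream == "rt":
            err = sub["accuracy"] == 0
            counts["error"] += int(err.sum())
            sub = sub[~err]
            fast = sub["rt_ms"] < FAST_RT_FLOOR_MS
            counts["fast_rt"] += int(fast.sum())
            sub = sub[~fast]
        kept_parts.append(sub)

    kept = pd.concat(kept_parts) if kept_parts else trials.iloc[0:0]

    if stream == "rt" and not kept.empty:
        fenced_parts = []
        for sid, sub in kept.groupby("subject_id", sort=False):
            rts = sub["rt_ms"].to_numpy(float)
            if len(rts) >= 4:
                lo, hi = _tukey_fences(rts)
                high = sub["rt_ms"] > hi
                low = sub["rt_ms"] < lo
                counts["iqr_high"] += int(high.sum())
                counts["iqr_low"] += int(low.sum())
                sub = sub[~(high | low)]
            fenced_parts.append(sub)
        kept = pd.concat(fenced_parts)

    kept = kept.reset_index(drop=True)
    report = ExclusionReport(trials_removed=counts, n_input=len(trials),
                             n_output=len(kept), stream=stream)
    return kept, report


def congruency_effects(acc_trials: pd.DataFrame, rt_trials: pd.DataFrame | None = None):
    """Per-subject congruency effects and group summaries.

    ``acc_effect = accuracy(congruent) - accuracy(incongruent)`` from the
    accuracy-stream table; ``rt_effect = mean RT(incongruent) - mean
    RT(congruent)`` from the rt-stream table (defaults to ``acc_trials``
    restricted to correct responses).  Subjects missing a condition get a
    missing effect.
    """
    acc_trials = validate_trials(acc_trials)
    if rt_trials is None:
        rt_trials = acc_trials[acc_trials["accuracy"] == 1]
    rt_trials = validate_trials(rt_trials)

    acc = (acc_trials.groupby(["subject_id", "group", "congruency"])["accuracy"]
           .mean().unstack("congruency"))
    rt = (rt_trials.groupby(["subject_id", "group", "congruency"])["rt_ms"]
          .mean().unstack("congruency"))

    acc = acc.reindex(columns=["congruent", "incongruent"])
    rt = rt.reindex(index=acc.index, columns=["congruent", "incongruent"])
    per_subject = pd.DataFrame(index=acc.index).reset_index()
    for col in ("congruent", "incongruent"):
        per_subject[f"acc_{col}"] = acc[col].to_numpy()
        per_subject[f"rt_{col}"] = rt[col].to_numpy()
    per_subject["acc_effect"] = per_subject["acc_congruent"] - per_subject["acc_incongruent"]
    per_subject["rt_effect"] = per_subject["rt_incongruent"] - per_subject["rt_congruent"]

    def _summary(series: pd.Series) -> pd.Series:
        s = series.dropna()
        return pd.Series({"mean": s.mean(), "median": s.median(),
                          "q1": s.quantile(0.25), "q3": s.quantile(0.75),
                          "n": len(s)})

    group_summary = (per_subject.groupby("group")[["acc_effect", "rt_effect"]]
                     .apply(lambda g: pd.concat({c: _summary(g[c]) for c in g.columns}))
                     .unstack())
    return per_subject, group_summary
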