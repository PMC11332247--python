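"""Group comparisons of fitted parameters: t-tests, Welch correction, Cohen's d.

The variance-equality rule deciding between the pooled and Welch t is
Levene's test at alpha = 0.05 on raw samples (an F-ratio test when only
summary statistics are available); ``variance_rule`` can force either mode.
Cohen's d always uses the pooled SD, with a 95% CI from the noncentral-t
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VARIANCE_RULES = ("auto", "pooled", "welch")


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    d: float
    d_ci: tuple
    welch_used: bool
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "d": self.d,
                "d_ci_low": self.d_ci[0], "d_ci_high": self.d_ci[1],
                "welch_used": self.welch_used,
                "group_a": {"mean": self.mean_a, "sd": self.sd_a, "n": self.n_a},
                "group_b": {"mean": self.mean_b, "sd": self.sd_b, "n": self.n_b}}


def _d_confidence_interval(t: float, df: float, n_a: int, n_b: int,
                           level: float = 0.95) -> tuple:
    """CI for Cohen's d by inverting the noncentral-t distribution."""
    k = math.sqrt(1.0 / n_a + 1.0 / n_b)
    alpha = 1.0 - level

    def _solve(target_p):
        lo, hi = t - 20.0, t + 20.0
        f = lambda ncp: stats.nct.cdf(t, df, ncp) - target_p
        try:
            from scipy.optimize import brentq
            return brentq(f, lo, hi, xtol=1e-8)
        except ValueError:
            return float("nan")

    ncp_low = _solve(1.0 - alpha / 2.0)
    ncp_high = _solve(alpha / 2.0)
    return (ncp_low * k, ncp_high * k)


def summary_from_stats(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int,
                       variance_rule: str = "pooled") -> TestResult:
    """Independent two-sample t-test and Cohen's d from sufficient statistics."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if variance_rule not in VARIANCE_RULES:
        raise ValueError(f"variance_rule must be one of {VARIANCE_RULES}")

    if variance_rule == "auto":
        # F-ratio test of variance equality (summary-stat surrogate for Levene)
        if sd_a == 0 or sd_b == 0:
            welch = sd_a != sd_b
        else:
            f = (sd_a / sd_b) ** 2
            p_var = 2.0 * min(stats.f.cdf(f, n_a - 1, n_b - 1),
                              stats.f.sf(f, n_a - 1, n_b - 1))
            welch = p_var < 0.05
    else:
        welch = variance_rule == "welch"

    var_a, var_b = sd_a**2, sd_b**2
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    sp = math.sqrt(pooled_var)

    if welch:
        se2 = var_a / n_a + var_b / n_b
        se = math.sqrt(se2)
        df = se2**2 / ((var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)) \
            if se2 > 0 else float("nan")
    else:
        se = sp * math.sqrt(1.0 / n_a + 1.0 / n_b)
        df = float(n_a + n_b - 2)

    diff = mean_a - mean_b
    if se == 0:
        t = float("nan") if diff == 0 else math.copysign(float("inf"), diff)
        p = float("nan") if diff == 0 else 0.0
    else:
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df)

    d = diff / sp if sp > 0 else float("nan")
    # the CI uses the pooled-df geometry regardless of the Welch flag,
    # matching the convention of reporting pooled-SD d alongside a Welch t
    d_ci = _d_confidence_interval(d / math.sqrt(1 / n_a + 1 / n_b),
                                  n_a + n_b - 2, n_a, n_b) \
        if np.isfinite(d) else (float("nan"), float("nan"))

    return TestResult(t=t, df=df, p=p, d=d, d_ci=d_ci, welch_used=welch,
                      mean_a=mean_a, sd_a=sd_a, n_a=n_a,
                      mean_b=mean_b, sd_b=sd_b, n_b=n_b)


def independent_t(scores_a, scores_b, variance_rule: str = "auto") -> TestResult:
    """Independent-samples comparison of two score vectors."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variance_rule == "auto":
        if np.var(a) == 0 and np.var(b) == 0:
            variance_rule = "pooled"
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p_lev = stats.levene(a, b)
            variance_rule = "welch" if (np.isfinite(p_lev) and p_lev < 0.05) \
                else "pooled"
    return summary_from_stats(float(a.mean()), float(a.std(ddof=1)), a.size,
                              float(b.mean()), float(b.std(ddof=1)), b.size,
                              variance_rule=variance_rule)


def shift_difference_scores(param_table: pd.DataFrame,
                            parameter: str = "shift_delta") -> pd.DataFrame:
    """Per-subject congruent-minus-incongruent difference score.

    ``parameter`` is the stem of a congruency-specific parameter pair, e.g.
    ``shift_delta`` (boundary adjustment) or ``v`` (DDM drift rate).
    Subjects missing either value are dropped.
    """
    col_c, col_i = f"{parameter}_congruent", f"{parameter}_incongruent"
    for col in (col_c, col_i):
        if col not in param_table.columns:
            raise ValueError(f"parameter table lacks column {col!r}")
    out = param_table[["subject_id"]].copy()
    if "group" in param_table.columns:
        out["group"] = param_table["group"]
    out["score"] = param_table[col_c] - param_table[col_i]
    return out.dropna(subset=["score"]).reset_index(drop=True)


def compare_groups(param_table: pd.DataFrame, parameter: str = "shift_delta",
                   group_a: str = "reward_congruent",
                   group_b: str = "reward_incongruent",
                   variance_rule: str = "auto") -> TestResult:
    """Group comparison of the congruency difference score of ``parameter``."""
    scores = shift_difference_scores(param_table, parameter)
    a = scores.loc[scores["group"] == group_a, "score"]
    b = scores.loc[scores["group"] == group_b, "score"]
    return independent_t(a, b, variance_rule=variance_rule)
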