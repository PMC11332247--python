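"""Conditional accuracy functions: accuracy per RT quantile bin.

Bin edges are computed across subjects, pooled over both congruency
conditions within each group (so the congruent and incongruent curves share
a common x-axis); ``pool="congruency"`` computes edges per congruency
instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trialtable import validate_trials


def conditional_accuracy(trials: pd.DataFrame, n_bins: int = 5,
                         pool: str = "group") -> pd.DataFrame:
    """Accuracy per RT quantile bin x congruency x group.

    ``trials`` must carry RT and accuracy for scored trials (the accuracy
    analysis stream: errors retained, nulls removed).  Returns a tidy table
    with columns group, congruency, quintile, accuracy, n_trials,
    edge_low_ms, edge_high_ms.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if pool not in ("group", "congruency"):
        raise ValueError("pool must be 'group' or 'congruency'")
    trials = validate_trials(trials)
    scored = trials[trials["rt_ms"].notna() & trials["accuracy"].notna()]
    if len(scored) < n_bins:
        raise ValueError("fewer scored trials than bins")

    rows = []
    for group, gsub in scored.groupby("group", sort=True):
        if pool == "group":
            edges = np.quantile(gsub["rt_ms"].to_numpy(float),
                                np.linspace(0, 1, n_bins + 1))
        for congruency, csub in gsub.groupby("congruency", sort=True):
            rts = csub["rt_ms"].to_numpy(float)
            acc = csub["accuracy"].to_numpy(float)
            if pool == "congruency":
                edges = np.quantile(rts, np.linspace(0, 1, n_bins + 1))
            # right-inclusive bins; the lowest edge is pulled down so the
            # fastest trial lands in bin 1
            idx = np.clip(np.searchsorted(edges[1:-1], rts, side="left"),
                          0, n_bins - 1)
            for q in range(n_bins):
                sel = idx == q
                rows.append({
                    "group": group, "congruency": congruency, "quintile": q + 1,
                    "accuracy": float(acc[sel].mean()) if sel.any() else np.nan,
                    "n_trials": int(sel.sum()),
                    "edge_low_ms": float(edges[q]),
                    "edge_high_ms": float(edges[q + 1]),
                })
    return pd.DataFrame(rows)
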