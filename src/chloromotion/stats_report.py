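"""Welch two-sample comparisons of per-leaf Δindex distributions.

Between-half index differences are compared across irradiance conditions
with the unequal-variances t-test:

    t = (mean_a − mean_b) / sqrt(s_a²/n_a + s_b²/n_b)

with Welch–Satterthwaite degrees of freedom and a two-sided p-value.
Multi-group summaries report unadjusted pairwise p-values: no familywise
correction is applied (the flag is carried in the output so downstream
consumers know).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indices import IndexDelta, deltas_to_frame


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float


def welch_t(
    a: np.ndarray, b: np.ndarray, label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Welch's t-test between two samples of scalars.

    Requires at least two observations per group. When both samples have
    zero variance and equal means, the comparison degenerates and t = 0,
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")

    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a == 0.0 and sd_b == 0.0:
        if a.mean() == b.mean():
            t_stat, df, p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            t_stat, df, p = np.inf if a.mean() > b.mean() else -np.inf, float(
                a.size + b.size - 2
            ), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparison(
        label_a, label_b, a.size, b.size,
        float(a.mean()), float(b.mean()), float(sd_a), float(sd_b),
        t_stat, df, p,
    )


def delta_summary(
    deltas: list[IndexDelta],
    group_by: tuple[str, ...] = ("index_name", "condition"),
    compare_on: str = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-group summary plus pairwise Welch comparisons.

    Returns ``(summary, comparisons)``: per-group n / mean Δ / SD, and one
    Welch row per index for each pair of ``compare_on`` levels. Groups
    with n < 2 are dropped from the comparisons with a warning column.
    """
    if not deltas:
        raise ValueError("no deltas to summarise")
    df = deltas_to_frame(deltas)
    summary = (
        df.groupby(list(group_by), dropna=False)["delta"]
        .agg(n="count", mean_delta="mean", sd_delta=lambda x: x.std(ddof=1))
        .reset_index()
    )

    rows = []
    other_keys = [k for k in group_by if k != compare_on]
    for keys, sub in df.groupby(other_keys, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        levels = [l for l in sub[compare_on].dropna().unique()]
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                xa = sub.loc[sub[compare_on] == levels[i], "delta"].to_numpy()
                xb = sub.loc[sub[compare_on] == levels[j], "delta"].to_numpy()
                if xa.size < 2 or xb.size < 2:
                    continue
                cmp_res = welch_t(xa, xb, str(levels[i]), str(levels[j]))
                row = dict(zip(other_keys, keys))
                row.update(
                    group_a=cmp_res.label_a,
                    group_b=cmp_res.label_b,
                    n_a=cmp_res.n_a,
                    n_b=cmp_res.n_b,
                    mean_a=cmp_res.mean_a,
                    mean_b=cmp_res.mean_b,
                    t=cmp_res.t,
                    df=cmp_res.df,
                    p=cmp_res.p,
                    familywise_corrected=False,
                )
                rows.append(row)
    comparisons = pd.DataFrame(rows)
    return summary, comparisons
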