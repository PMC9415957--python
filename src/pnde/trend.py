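"""Ordered-alternative trend testing across independent groups.

The Jonckheere-Terpstra (JT) statistic for groups given in a hypothesized
order is the sum over ordered group pairs of Mann-Whitney counts,
``#(x < y) + 0.5 * #(x == y)`` for x in the earlier and y in the later group.
Significance uses the normal approximation with the tie-corrected null
variance; pairwise post-hoc comparisons are two-group JT statistics with a
Bonferroni adjustment, mirroring the columns of SPSS's pairwise output
(test statistic, standard error, standardized statistic, significance,
adjusted significance).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TrendTestResult", "jonckheere_terpstra", "pairwise_posthoc"]


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float       # JT statistic
    mean: float            # E[JT] under H0
    variance: float        # tie-corrected Var[JT] under H0
    z: float
    pvalue: float          # two-sided
    n_groups: int
    group_sizes: tuple[int, ...]


def _mw_count(x: np.ndarray, y: np.ndarray) -> float:
    """#(x < y) + 0.5 #(x == y) over all cross pairs, vectorized."""
    diff = y[None, :] - x[:, None]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _tie_groups(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts.astype(float)


def jonckheere_terpstra(groups: Sequence[Sequence[float]]) -> TrendTestResult:
    """JT test for a monotone trend across groups in the stated order.

    The null mean is ``(N^2 - sum n_i^2) / 4``; the variance uses the
    tie-corrected expansion so tied observations (common for discretized
    scores) do not inflate significance.  The p-value is two-sided from the
    normal approximation.
    """
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    gs = [g for g in gs if g.size > 0]
    if len(gs) < 2:
        raise ValueError("need at least 2 non-empty groups")
    jt = sum(_mw_count(gs[i], gs[j]) for i, j in combinations(range(len(gs)), 2))

    n = np.array([g.size for g in gs], dtype=float)
    N = n.sum()
    mean = (N ** 2 - (n ** 2).sum()) / 4.0
    t = _tie_groups(np.concatenate(gs))
    var = (
        (N * (N - 1) * (2 * N + 5)
         - (n * (n - 1) * (2 * n + 5)).sum()
         - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
        + ((n * (n - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * N * (N - 1))
    )
    if N > 2:  # this tie term needs three distinct pooled observations
        var += ((n * (n - 1) * (n - 2)).sum() * (t * (t - 1) * (t - 2)).sum()) \
            / (36.0 * N * (N - 1) * (N - 2))
    if var < -1e-9:
        raise ValueError(f"negative null variance {var}")
    if var <= 0:
        # every pooled observation tied: the statistic is degenerate
        z, p, var = 0.0, 1.0, 0.0
    else:
        z = (jt - mean) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return TrendTestResult(statistic=jt, mean=mean, variance=var, z=z,
                           pvalue=p, n_groups=len(gs),
                           group_sizes=tuple(int(x) for x in n))


def pairwise_posthoc(groups: Sequence[Sequence[float]],
                     labels: Sequence[str] | None = None) -> pd.DataFrame:
    """All-pairs two-group rank comparisons with Bonferroni adjustment.

    Each pair is tested with the two-group JT (equivalently Mann-Whitney)
    statistic under the tie-corrected normal approximation.  The reported
    significance is the upper-tail probability of |z| and the adjusted
    significance is ``min(1, significance * n_comparisons)``, following the
    convention of SPSS's nonparametric pairwise-comparison tables.
    """
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels length must match number of groups")
    pairs = list(combinations(range(len(gs)), 2))
    rows = []
    for i, j in pairs:
        x, y = gs[i], gs[j]
        u = _mw_count(x, y)
        n1, n2 = float(x.size), float(y.size)
        N = n1 + n2
        t = _tie_groups(np.concatenate([x, y]))
        var = n1 * n2 / 12.0 * ((N + 1) - ((t ** 3 - t).sum()) / (N * (N - 1)))
        se = float(np.sqrt(var))
        z = (u - n1 * n2 / 2.0) / se if se > 0 else 0.0
        p = float(sps.norm.sf(abs(z)))
        rows.append({
            "sample_1": labels[i],
            "sample_2": labels[j],
            "statistic": u,
            "std_error": se,
            "std_statistic": z,
            "significance": p,
            "adj_significance": min(1.0, p * len(pairs)),
        })
    return pd.DataFrame(rows)
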