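"""Nonparametric k-group tests: Kruskal-Wallis plus Nemenyi and Dunn
post-hoc pairwise comparisons on mean ranks, with tie correction.

The Nemenyi p-values use the studentized-range distribution with infinite
degrees of freedom on the rank-based q statistic; Dunn's z-tests use the
normal approximation with a tie-corrected variance and a configurable
multiple-comparison adjustment (Bonferroni by default).
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p; (0, 1) when all values tie."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


def _rank_setup(groups: Sequence[np.ndarray]):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    i = 0
    for g in arrs:
        mean_ranks.append(ranks[i : i + len(g)].mean())
        i += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    sizes = np.array([len(g) for g in arrs])
    return np.array(mean_ranks), sizes, n, tie_sum


def nemenyi(groups: Sequence[np.ndarray], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Nemenyi p-values on mean ranks (symmetric, unit diagonal)."""
    mean_ranks, sizes, n, tie_sum = _rank_setup(groups)
    k = len(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    tie_factor = 1.0 - tie_sum / (n**3 - n) if n > 1 else 1.0
    out = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0) * (1.0 / sizes[i] + 1.0 / sizes[j]) * tie_factor
        )
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, np.inf)) if se > 0 else 1.0
        out.iat[i, j] = out.iat[j, i] = min(1.0, p)
    return out


def dunn(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    p_adjust: str | None = "bonferroni",
) -> pd.DataFrame:
    """Pairwise Dunn z-test p-values on mean ranks with tie correction."""
    mean_ranks, sizes, n, tie_sum = _rank_setup(groups)
    k = len(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            raw.append(1.0)
            continue
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * float(stats.norm.sf(z)))
    if p_adjust == "bonferroni":
        adj = [min(1.0, p * len(pairs)) for p in raw]
    elif p_adjust is None:
        adj = raw
    else:
        from statsmodels.stats.multitest import multipletests

        adj = list(multipletests(raw, method=p_adjust)[1])
    out = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for (i, j), p in zip(pairs, adj):
        out.iat[i, j] = out.iat[j, i] = p
    return out
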