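"""Nonparametric group comparisons for proportions and interaction scores.

Two groups are compared by the Wilcoxon rank-sum (Mann-Whitney) test --
exact for small tie-free samples, tie-corrected normal approximation
otherwise.  Three or more groups use Kruskal-Wallis with Dunn's post hoc
pairwise z-tests, multiplicity-adjusted (Holm by default).
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "proportions_from_counts",
    "wilcoxon_two_group",
    "kruskal_dunn",
]


def proportions_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a sample x cell-type count table to proportions."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)}")
    return counts.div(totals, axis=0)


def wilcoxon_two_group(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the Mann-Whitney U statistic (for the first group) and the
    two-sided p.  Exact enumeration when both groups are small (< 8) and
    tie-free; otherwise the tie-corrected normal approximation.  When every
    observation is tied the test carries no information and p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size < 8 and y.size < 8
    if small and not has_ties:
        method = "exact"
    elif small:
        # exact enumeration of the tied null via full permutation
        method = sps.PermutationMethod(n_resamples=np.inf)
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _dunn_pairwise(
    samples: Mapping[str, np.ndarray], adjust: str
) -> pd.DataFrame:
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        size = samples[g].size
        mean_rank[g] = float(ranks[start : start + size].mean())
        start += size
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        na, nb = samples[a].size, samples[b].size
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust == "none":
        out["p_adj"] = out["p_raw"]
    else:
        out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    return out


def kruskal_dunn(
    values: Sequence[float],
    labels: Sequence[str],
    adjust: str = "holm",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post hoc z-tests.

    Returns (H, omnibus p, pairwise table with raw and adjusted p).  Dunn's
    z uses the pooled tie-corrected rank variance; the default multiplicity
    adjustment is Holm.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use wilcoxon_two_group for two")
    samples = {g: values[labels == g] for g in groups}
    if any(s.size == 0 for s in samples.values()):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(list(samples.values()))
    if np.all(pooled == pooled[0]):
        pairwise = _dunn_pairwise(samples, adjust)
        return 0.0, 1.0, pairwise
    h, p = sps.kruskal(*samples.values())
    pairwise = _dunn_pairwise(samples, adjust)
    return float(h), float(p), pairwise
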