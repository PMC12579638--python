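"""Interaction-frequency statistics per directed cell-type pair.

How diverse is the communication between each ordered pair of cell types in
a biopsy?  Interactions are first filtered to those robustly detected
(aggregate rank <= 0.1, a p-value proxy), then counted per (sender,
receiver) pair and normalized by the sample's total detected count so each
sample yields a proportion vector summing to one.  Group contrasts use the
log2 fold change of medians (with a 0.001 pseudocount guarding zeros) and a
two-sided Wilcoxon rank-sum test per pair.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RankedInteraction
from .stats import wilcoxon_two_group

__all__ = [
    "filter_significant",
    "pair_frequencies",
    "median_log2_fc",
    "compare_pair_frequencies",
]


def filter_significant(
    records: Sequence[RankedInteraction], cutoff: float = 0.1
) -> list[RankedInteraction]:
    """Keep interactions with aggregate rank <= cutoff (boundary inclusive)."""
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    return [r for r in records if r.aggregate_rank <= cutoff]


def pair_frequencies(
    records: Mapping[str, Sequence[RankedInteraction]],
    cell_types: Sequence[str],
) -> pd.DataFrame:
    """Per-sample proportion of detected interactions per directed pair.

    Expects already-filtered records.  Columns cover every ordered pair of
    ``cell_types`` including self-pairs, labelled ``"sender->receiver"``;
    pairs with no detected interaction get 0, and a sample with no passing
    interactions at all keeps an all-zero row.
    """
    pairs = [(s, r) for s in cell_types for r in cell_types]
    columns = [f"{s}->{r}" for s, r in pairs]
    samples = sorted(records)
    out = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=columns)
    for sample in samples:
        counts: dict[str, int] = {}
        for rec in records[sample]:
            col = f"{rec.key.sender}->{rec.key.receiver}"
            if col not in out.columns:
                raise KeyError(
                    f"sample {sample}: cell type pair {col} not covered by cell_types"
                )
            counts[col] = counts.get(col, 0) + 1
        total = sum(counts.values())
        if total:
            for col, cnt in counts.items():
                out.loc[sample, col] = cnt / total
    return out


def median_log2_fc(
    group_a: pd.DataFrame, group_b: pd.DataFrame, pseudocount: float = 0.001
) -> pd.Series:
    """Per-pair log2((median_A + c) / (median_B + c)).

    The pseudocount keeps the statistic defined when a pair is absent from
    every sample of a group (median 0), and makes equal medians -- including
    the all-zero case -- map exactly to 0.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be nonempty")
    med_a = group_a.median(axis=0)
    med_b = group_b.median(axis=0)
    return pd.Series(
        np.log2((med_a + pseudocount) / (med_b + pseudocount)),
        index=group_a.columns,
        name="log2_fc",
    )


def compare_pair_frequencies(
    matrix: pd.DataFrame, labels: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per pair column between two groups.

    Returns a DataFrame indexed by pair with columns statistic, p_value,
    group sizes.
    """
    labels = pd.Series(labels).reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    a, b = groups
    rows = []
    for col in matrix.columns:
        stat, p = wilcoxon_two_group(
            matrix.loc[labels == a, col].to_numpy(),
            matrix.loc[labels == b, col].to_numpy(),
        )
        rows.append({"pair": col, "statistic": stat, "p_value": p,
                     f"n_{a}": int((labels == a).sum()), f"n_{b}": int((labels == b).sum())})
    return pd.DataFrame(rows).set_index("pair")


def long_format(values: pd.Series) -> pd.DataFrame:
    """Heatmap-ready (sender, receiver, value) long table for a per-pair series."""
    rows = []
    for pair, value in values.items():
        sender, receiver = str(pair).split("->")
        rows.append({"sender": sender, "receiver": receiver, "value": value})
    return pd.DataFrame(rows)
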