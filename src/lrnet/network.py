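"""Co-correlate network around selected interaction features.

For each model-selected "center" feature, Pearson correlations are computed
against every other interaction in the *unimputed* rank matrix using
pairwise-complete samples -- including interactions that never survived the
missingness filter, since correlation tolerates holes.  The strongest
``k`` partners per center (by |r|, positive or negative) form the network,
exported as GraphML plus a plain TSV edge list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationEdge",
    "pairwise_pearson",
    "top_k_edges",
    "export_network",
]


@dataclass(frozen=True)
class CorrelationEdge:
    center_feature: str
    partner_feature: str
    r: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


def pairwise_pearson(
    centers: Sequence[str],
    matrix: pd.DataFrame,
    min_overlap: int = 5,
) -> list[CorrelationEdge]:
    """Pearson r of each center against every other column.

    Uses the samples where both columns are present; pairs with fewer than
    ``min_overlap`` shared samples, or zero variance on the overlap, are
    skipped.  Center-center duplicates are kept once (undirected edge).
    """
    missing = [c for c in centers if c not in matrix.columns]
    if missing:
        raise KeyError(f"center features not in matrix: {missing}")
    center_set = set(centers)
    edges: list[CorrelationEdge] = []
    seen: set[frozenset[str]] = set()
    values = matrix.to_numpy(float)
    col_index = {c: j for j, c in enumerate(matrix.columns)}
    for center in centers:
        ci = col_index[center]
        x = values[:, ci]
        if np.isnan(x).all():
            raise ValueError(f"center column {center!r} is entirely missing")
        for partner in matrix.columns:
            if partner == center:
                continue
            if partner in center_set and frozenset((center, partner)) in seen:
                continue
            yv = values[:, col_index[partner]]
            both = ~np.isnan(x) & ~np.isnan(yv)
            n_pairs = int(both.sum())
            if n_pairs < min_overlap:
                continue
            xs, ys = x[both], yv[both]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            edges.append(CorrelationEdge(center, str(partner), r, n_pairs))
            if partner in center_set:
                seen.add(frozenset((center, partner)))
    return edges


def top_k_edges(
    edges: Sequence[CorrelationEdge], k: int = 5
) -> dict[str, list[CorrelationEdge]]:
    """The k strongest partners per center by |r|.

    Ties in |r| break toward the lexicographically smaller partner label so
    the output is deterministic.  Partners that are themselves centers stay
    eligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_center: dict[str, list[CorrelationEdge]] = {}
    for e in edges:
        by_center.setdefault(e.center_feature, []).append(e)
    out: dict[str, list[CorrelationEdge]] = {}
    for center, lst in by_center.items():
        ranked = sorted(lst, key=lambda e: (-abs(e.r), e.partner_feature))
        out[center] = ranked[:k]
    return out


def export_network(
    per_center: Mapping[str, Sequence[CorrelationEdge]],
    path_prefix: str | Path,
    center_annotations: Mapping[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write GraphML and a TSV edge list; returns both paths.

    ``center_annotations`` maps center features to an enrichment direction
    (free text, e.g. which group the feature is enriched in).  Centers with
    no surviving edges still appear as isolated nodes.
    """
    prefix = Path(path_prefix)
    annotations = center_annotations or {}
    graph = nx.Graph()
    for center in sorted(per_center):
        graph.add_node(
            center, is_center=True, enrichment=annotations.get(center, "")
        )
    rows = []
    for center in sorted(per_center):
        for e in per_center[center]:
            if not graph.has_node(e.partner_feature):
                graph.add_node(e.partner_feature, is_center=False, enrichment="")
            graph.add_edge(
                center, e.partner_feature, weight=e.r, sign=e.sign, n_pairs=e.n_pairs
            )
            rows.append(
                {
                    "center": center,
                    "partner": e.partner_feature,
                    "r": e.r,
                    "n_pairs": e.n_pairs,
                    "sign": e.sign,
                }
            )
    graphml_path = prefix.with_suffix(".graphml")
    tsv_path = prefix.with_suffix(".edges.tsv")
    nx.write_graphml(graph, graphml_path)
    pd.DataFrame(rows, columns=["center", "partner", "r", "n_pairs", "sign"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    return graphml_path, tsv_path
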