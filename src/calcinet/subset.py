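"""Labeled-subset analysis: induced subgraph, cross-connectivity, rates.

When a subset of cells carries a label (for instance a second fluorescent
reporter, or a genetic perturbation marker), three questions arise: how is
the subset wired internally, how strongly does it talk to the rest of the
network, and how active is it?  This module answers them with the induced
subgraph on labeled cells (same threshold, same weights), the
labeled-to-unlabeled connection proportion

    LtU = (# edges with exactly one labeled endpoint)
          / (n_labeled * n_unlabeled)

— realized cross edges over all possible cross pairs, each undirected edge
counted once — and the mean event rate restricted to the labeled cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BinaryRaster, FunctionalGraph
from .graph_metrics import (
    GraphMetrics,
    clustering_coefficient,
    degree_stats,
    global_efficiency,
)
from .population import events_per_min

__all__ = ["SubsetReport", "subset_graph", "ltu_proportion", "subset_summary"]


@dataclass
class SubsetReport:
    subset_ids: list[str]
    ltu: float
    subset_metrics: GraphMetrics
    freq_labeled: float


def _labeled_nodes(g: FunctionalGraph, label: str) -> list[str]:
    nodes = [
        n for n, d in g.graph.nodes(data=True) if d.get("label") == label
    ]
    if not nodes:
        avail = sorted(
            {d["label"] for _, d in g.graph.nodes(data=True) if "label" in d}
        )
        raise ValueError(
            f"label {label!r} not present; available labels: {avail}"
        )
    return nodes


def subset_graph(g: FunctionalGraph, label: str) -> FunctionalGraph:
    """Induced subgraph on the cells carrying ``label`` (same theta/weights)."""
    nodes = _labeled_nodes(g, label)
    sub = g.graph.subgraph(nodes).copy()
    return FunctionalGraph(graph=sub, theta=g.theta)


def ltu_proportion(g: FunctionalGraph, label: str) -> float:
    """Realized labeled-to-unlabeled edges over all possible cross pairs."""
    labeled = set(_labeled_nodes(g, label))
    unlabeled = [n for n in g.graph.nodes if n not in labeled]
    if not unlabeled:
        raise ValueError("no unlabeled cells; LtU undefined")
    cross = sum(
        1 for u, v in g.graph.edges if (u in labeled) != (v in labeled)
    )
    return cross / (len(labeled) * len(unlabeled))


def subset_summary(
    g: FunctionalGraph,
    b: BinaryRaster,
    label: str,
    frame_interval_s: float | None = None,
    events_mode: str = "onsets",
) -> SubsetReport:
    """Bundle subset-graph metrics, LtU and the labeled event rate."""
    sub = subset_graph(g, label)
    ids = sub.nodes()
    degs = degree_stats(sub)
    metrics = GraphMetrics(
        degrees=degs.degrees,
        mean_degree=degs.mean_degree,
        clustering_coeff=clustering_coefficient(sub),
        global_efficiency=(
            global_efficiency(sub) if sub.n_nodes >= 2 else float("nan")
        ),
    )
    idx = [b.cell_ids.index(cid) for cid in ids]
    freq = events_per_min(
        b,
        frame_interval_s=frame_interval_s,
        subset=np.asarray(idx, dtype=int),
        mode=events_mode,
    )
    return SubsetReport(
        subset_ids=ids,
        ltu=ltu_proportion(g, label),
        subset_metrics=metrics,
        freq_labeled=freq,
    )
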