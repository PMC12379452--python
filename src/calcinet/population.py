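"""Population-activity summaries: active-cell fraction, event rates,
hierarchical raster ordering.

An *event* is a rising edge of the binarized trace (a 0-to-1 transition;
a 1 in the first frame counts as an onset).  Rates are reported per minute
with recording duration = n_time * frame_interval_s.  An alternative
``mode="frames"`` counts active frames instead of onsets, for users whose
activity definition is occupancy rather than transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .core_io import BinaryRaster, NormalizedTraces

__all__ = [
    "ActivityTrace",
    "ClusterOrder",
    "active_percentage",
    "events_per_min",
    "cluster_traces",
]

_LINKAGES = ("ward", "complete", "average", "single")


@dataclass
class ActivityTrace:
    """Percent of cells active at each frame, with the time axis in seconds."""

    percent_active: np.ndarray
    time_s: np.ndarray


@dataclass
class ClusterOrder:
    """Dendrogram leaf ordering of cells for raster display.

    ``merge_tree`` is the scipy linkage matrix (pairs merged, heights,
    cluster sizes).
    """

    ordering: np.ndarray
    linkage_method: str
    merge_tree: np.ndarray


def active_percentage(b: BinaryRaster) -> ActivityTrace:
    """Percent of active cells per frame: 100 * mean over cells of the raster."""
    pct = 100.0 * b.values.mean(axis=0)
    time_s = np.arange(b.n_time) * b.frame_interval_s
    return ActivityTrace(percent_active=pct, time_s=time_s)


def _onsets(row: np.ndarray) -> int:
    # rising edges; a 1 at t=0 is an onset
    d = np.diff(row.astype(np.int8), prepend=0)
    return int((d == 1).sum())


def events_per_min(
    b: BinaryRaster,
    frame_interval_s: Optional[float] = None,
    subset: Optional[Sequence[int] | np.ndarray] = None,
    mode: str = "onsets",
) -> float:
    """Mean event rate (events/min) over the selected cells.

    ``subset`` selects cells by integer index or boolean mask; default is
    the whole population.  ``mode="onsets"`` counts 0-to-1 transitions;
    ``mode="frames"`` counts active frames.
    """
    if frame_interval_s is None:
        frame_interval_s = b.frame_interval_s
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    v = b.values
    if subset is not None:
        sel = np.asarray(subset)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        if sel.size == 0:
            raise ValueError("empty cell subset")
        v = v[sel]
    duration_min = v.shape[1] * frame_interval_s / 60.0
    if mode == "onsets":
        counts = np.array([_onsets(row) for row in v], dtype=float)
    elif mode == "frames":
        counts = v.sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown events mode {mode!r}")
    return float(counts.mean() / duration_min)


def cluster_traces(
    n: NormalizedTraces,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> ClusterOrder:
    """Agglomerative clustering of cells on their trace row vectors.

    Returns the dendrogram leaf ordering (used to sort raster rows so that
    co-active cells sit together) and the merge tree.  Linkage is one of
    ward / complete / average / single; Ward requires the Euclidean
    metric.  scipy's deterministic merge procedure fixes tie-breaks, so
    the ordering is reproducible for a fixed input row order.
    """
    if linkage not in _LINKAGES:
        raise ValueError(
            f"unknown linkage {linkage!r}; choose from {_LINKAGES}"
        )
    if n.n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    Z = hierarchy.linkage(n.values, method=linkage, metric=metric)
    order = hierarchy.leaves_list(Z)
    return ClusterOrder(
        ordering=np.asarray(order, dtype=int),
        linkage_method=linkage,
        merge_tree=Z,
    )
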