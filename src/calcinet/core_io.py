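"""Domain containers and CSV/GraphML input-output.

The analysis operates on two user-supplied tables:

* a traces table, rows = cells/ROIs and columns = time points, holding raw
  or pre-processed fluorescence values (arbitrary units);
* a coordinates table with columns ``X``, ``Y``, ``Cell`` and an optional
  ``Label`` column marking membership of a cell subset (e.g. cells carrying
  a second fluorescent reporter).

Everything downstream (normalization, binarization, connectivity, graphs)
works on the containers defined here.  Cell identifiers are matched as
whitespace-trimmed strings so that mixed numeric/string ids coming from
spreadsheet exports align correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TraceMatrix",
    "CellTable",
    "NormalizedTraces",
    "BinaryRaster",
    "FunctionalGraph",
    "TracesFormatError",
    "AlignmentError",
    "read_traces",
    "read_cells",
    "align_cells",
    "write_graph",
    "read_graph",
    "write_traces",
]


class TracesFormatError(ValueError):
    """Raised when an input table cannot be parsed or fails validation."""


class AlignmentError(ValueError):
    """Raised when trace ids and coordinate-table ids do not match."""


def _clean_ids(ids: Sequence) -> list[str]:
    """Cell ids are compared as trimmed strings (mixed CSV dialects)."""
    out = []
    for i in ids:
        s = str(i).strip()
        # "3.0" and "3" should collide to the same id for numeric columns
        if s.endswith(".0"):
            try:
                if float(s) == int(float(s)):
                    s = str(int(float(s)))
            except ValueError:
                pass
        out.append(s)
    return out


@dataclass
class TraceMatrix:
    """Fluorescence traces, one row per cell, one column per time frame.

    Parameters
    ----------
    values
        ``(n_cells, n_time)`` float array, finite.
    cell_ids
        Unique string identifiers, one per row.
    frame_interval_s
        Seconds per frame (e.g. 2.0 for a 0.5 Hz acquisition). Required
        explicitly because event rates and spectra are meaningless
        without it.
    """

    values: np.ndarray
    cell_ids: list[str]
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TracesFormatError("trace values must be a 2-D matrix")
        n_cells, n_time = self.values.shape
        if n_cells < 1:
            raise TracesFormatError("need at least one cell")
        if n_time < 2:
            raise TracesFormatError(
                f"need at least 2 time points, got {n_time}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TracesFormatError(
                f"non-finite value at cell {i} (id {self.cell_ids[i]!r}), "
                f"time index {j}"
            )
        self.cell_ids = _clean_ids(self.cell_ids)
        if len(self.cell_ids) != n_cells:
            raise TracesFormatError(
                f"{len(self.cell_ids)} ids for {n_cells} rows"
            )
        if len(set(self.cell_ids)) != n_cells:
            dupes = {i for i in self.cell_ids if self.cell_ids.count(i) > 1}
            raise TracesFormatError(f"duplicate cell ids: {sorted(dupes)}")
        if self.frame_interval_s <= 0:
            raise TracesFormatError("frame_interval_s must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording duration = n_time * frame_interval_s."""
        return self.n_time * self.frame_interval_s

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_time) * self.frame_interval_s


@dataclass
class CellTable:
    """Spatial coordinates and optional subset labels, aligned to traces.

    ``label`` entries are ``None`` for unlabeled cells; empty strings and
    NA values in the CSV are treated as unlabeled.
    """

    x: np.ndarray
    y: np.ndarray
    cell_ids: list[str]
    labels: Optional[list[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_ids = _clean_ids(self.cell_ids)
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            dupes = {i for i in self.cell_ids if self.cell_ids.count(i) > 1}
            raise TracesFormatError(
                f"duplicate Cell ids in coordinates table: {sorted(dupes)}"
            )
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise TracesFormatError("X/Y length does not match Cell ids")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TracesFormatError("non-finite coordinate value")
        if self.labels is not None and len(self.labels) != n:
            raise TracesFormatError("labels length does not match Cell ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def label_values(self) -> list[str]:
        """Distinct non-empty label values, sorted."""
        if self.labels is None:
            return []
        return sorted({l for l in self.labels if l is not None})

    def labeled_mask(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise AlignmentError("coordinates table has no Label column")
        return np.array([l == label for l in self.labels], dtype=bool)


@dataclass
class NormalizedTraces:
    """Per-cell normalized traces; ``method`` is ``minmax`` or ``zscore``.

    Min-max output lies in [0, 1]; z-score output is unbounded with per-cell
    mean 0 and unit sample variance.
    """

    values: np.ndarray
    cell_ids: list[str]
    frame_interval_s: float
    method: str = "minmax"

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryRaster:
    """Active/inactive states per cell and frame, values in {0, 1}."""

    values: np.ndarray
    cell_ids: list[str]
    frame_interval_s: float
    threshold_spec: str = "mean + 2*sd"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("raster values must be 0 or 1")
        self.values = v.astype(np.int8)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class FunctionalGraph:
    """Thresholded functional-connectivity graph.

    Wraps an undirected :class:`networkx.Graph` whose nodes are cell ids
    (with ``x``, ``y`` and optional ``label`` / ``community`` attributes)
    and whose edges carry the peak cross-correlation as ``weight``.
    ``theta`` is the edge-inclusion threshold used (``None`` = unfiltered).
    """

    graph: nx.Graph
    theta: Optional[float]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _is_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def read_traces(
    path: str | Path,
    frame_interval_s: float,
    transpose: bool = False,
) -> TraceMatrix:
    """Read a traces CSV (rows = cells, columns = time points).

    Header row and leading id column are auto-detected: the first row is
    taken as a header when any of its non-leading fields is non-numeric,
    and the first column is taken as cell ids when any of its body values
    is non-numeric.  Otherwise ids are synthesized as the 0-based row
    index.  ``transpose=True`` flips a time-in-rows export.

    Missing or non-numeric body cells are rejected with an error naming
    the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str, skipinitialspace=True)
    if raw.shape[0] == 0:
        raise TracesFormatError(f"{path}: empty file")

    first_row = [str(v) for v in raw.iloc[0, 1:]]
    has_header = any(not _is_numeric(v) for v in first_row if v != "nan")
    body = raw.iloc[1:] if has_header else raw

    first_col = [str(v) for v in body.iloc[:, 0]]
    has_id_col = any(not _is_numeric(v) for v in first_col if v != "nan")
    if has_id_col:
        ids = list(body.iloc[:, 0])
        data = body.iloc[:, 1:]
        col_offset = 1
    else:
        ids = [str(i) for i in range(body.shape[0])]
        data = body
        col_offset = 0

    values = np.empty(data.shape, dtype=float)
    for j, col in enumerate(data.columns):
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            r = int(np.argmax(bad.to_numpy()))
            raise TracesFormatError(
                f"{path}: non-numeric or missing value at data row {r}, "
                f"column {j + col_offset} (cell id {ids[r]!r})"
            )
        values[:, j] = converted.to_numpy()

    if transpose:
        values = values.T
        ids = [str(i) for i in range(values.shape[0])]
    return TraceMatrix(values, [str(i) for i in ids], frame_interval_s)


def read_cells(path: str | Path) -> CellTable:
    """Read the cell coordinates CSV (columns X, Y, Cell, optional Label).

    Column names are matched case-insensitively. Cells with an empty or
    missing Label value are unlabeled.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    colmap = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in ("x", "y", "cell") if c not in colmap]
    if missing:
        raise TracesFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    x = pd.to_numeric(df[colmap["x"]], errors="coerce")
    y = pd.to_numeric(df[colmap["y"]], errors="coerce")
    if x.isna().any() or y.isna().any():
        raise TracesFormatError(f"{path}: non-numeric X/Y coordinate")
    labels: Optional[list[Optional[str]]] = None
    if "label" in colmap:
        raw = df[colmap["label"]]
        labels = [
            None if (pd.isna(v) or str(v).strip() == "") else str(v).strip()
            for v in raw
        ]
    return CellTable(
        x=x.to_numpy(),
        y=y.to_numpy(),
        cell_ids=list(df[colmap["cell"]]),
        labels=labels,
    )


def align_cells(traces: TraceMatrix, cells: CellTable) -> CellTable:
    """Reorder a cell table to the trace row order, matching on ids.

    Raises :class:`AlignmentError` listing the symmetric difference when
    the two id sets do not agree.  The result is order-independent of the
    incoming table's row order.
    """
    t_ids, c_ids = set(traces.cell_ids), set(cells.cell_ids)
    if t_ids != c_ids:
        only_traces = sorted(t_ids - c_ids)
        only_cells = sorted(c_ids - t_ids)
        raise AlignmentError(
            "trace and coordinate ids differ; only in traces: "
            f"{only_traces}; only in coordinates: {only_cells}"
        )
    pos = {cid: k for k, cid in enumerate(cells.cell_ids)}
    order = [pos[cid] for cid in traces.cell_ids]
    labels = None
    if cells.labels is not None:
        labels = [cells.labels[k] for k in order]
    return CellTable(
        x=cells.x[order],
        y=cells.y[order],
        cell_ids=[cells.cell_ids[k] for k in order],
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_traces(t: TraceMatrix, path: str | Path) -> None:
    """Write traces as CSV in the same dialect :func:`read_traces` accepts."""
    df = pd.DataFrame(
        t.values,
        index=t.cell_ids,
        columns=[f"t{j}" for j in range(t.n_time)],
    )
    df.index.name = "Cell"
    df.to_csv(path)


def write_graph(
    g: FunctionalGraph, path: str | Path, format: str = "graphml"
) -> None:
    """Export a functional graph as GraphML or a flat edge CSV.

    GraphML round-trips nodes, weighted edges, coordinates, labels and
    community assignments; the edge CSV holds source,target,weight rows
    only.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g.graph, path)
    elif format == "edge_csv":
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1.0)}
            for u, v, d in g.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path: str | Path, theta: Optional[float] = None) -> FunctionalGraph:
    """Read a GraphML file written by :func:`write_graph`."""
    g = nx.read_graphml(Path(path))
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    return FunctionalGraph(graph=g, theta=theta)
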