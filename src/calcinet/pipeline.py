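"""One-command orchestration of the full analysis, with reporting.

Stage order: load -> normalize -> binarize -> population activity
(+ hierarchical clustering, event rate) -> connectivity -> graph build ->
metrics + communities -> subset analysis (when a label is given) -> PCA +
PSD -> report.  Every intermediate is written to the run directory as CSV
/ GraphML / JSON, figures are rendered from those artifacts, and the
summary report mirrors the classic per-sample feature table: Top5PC Var
(%), C_g, G_g, LtU, Freq., Freq. labeled.

The pipeline is fully deterministic: identical inputs and configuration
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import core_io, preprocess, population, connectivity as conn
from . import graph_metrics as gm
from . import spectra, subset as subset_mod
from .core_io import FunctionalGraph

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
    "render_figures",
    "USE_CASE_PRESET",
]

log = logging.getLogger("calcinet")


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, mirroring the CLI flags.

    Defaults follow the package defaults throughout: min-max
    normalization, binarization at mean + 2 sd, connectivity on the
    binarized signals over lags {-1, 0, +1}, edge threshold 0.3, Ward
    linkage.  ``network_threshold=None`` disables edge filtering.
    """

    frame_interval_s: float = 2.0
    normalization_method: str = "minmax"  # minmax | zscore
    binarize_k: float = 2.0
    cluster_linkage: str = "ward"
    cluster_metric: str = "euclidean"
    connectivity_lag_max: int = 1
    connectivity_source: str = "binarized"  # binarized | normalized
    network_threshold: Optional[float] = 0.3
    clustering_count_zero: bool = False
    events_mode: str = "onsets"  # onsets | frames
    subset_label: Optional[str] = None
    pca_orientation: str = "cells"  # cells | time
    psd_segment_len: Optional[int] = None
    psd_overlap_frac: float = 0.5
    psd_window: str = "hann"
    transpose_traces: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file; dotted keys (``network.threshold``) and flat
        keys (``network_threshold``) are both accepted."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for k, v in raw.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    flat[f"{k}_{k2}"] = v2
            else:
                flat[k] = v
        alias = {
            "normalization_method": "normalization_method",
            "binarize_k": "binarize_k",
            "cluster_linkage": "cluster_linkage",
            "cluster_metric": "cluster_metric",
            "connectivity_lag_max": "connectivity_lag_max",
            "connectivity_source": "connectivity_source",
            "network_threshold": "network_threshold",
            "network_clustering_count_zero": "clustering_count_zero",
            "events_mode": "events_mode",
            "subset_label": "subset_label",
            "pca_orientation": "pca_orientation",
            "psd_segment_len": "psd_segment_len",
            "psd_overlap_frac": "psd_overlap_frac",
            "psd_window": "psd_window",
            "frame_interval_s": "frame_interval_s",
            "transpose_traces": "transpose_traces",
        }
        kwargs = {}
        for k, v in flat.items():
            if k not in alias:
                raise ValueError(f"unknown config key {k!r}")
            if alias[k] == "network_threshold" and v == "none":
                v = None
            kwargs[alias[k]] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


#: the stricter published use-case settings (threshold 0.6, lag 1)
USE_CASE_PRESET = {"network_threshold": 0.6, "connectivity_lag_max": 1}


@dataclass
class PipelineReport:
    """Per-sample summary record plus provenance."""

    n_cells: int
    n_time: int
    top5pc_var_percent: float
    clustering_coeff: float
    global_efficiency: float
    mean_degree: float
    freq_events_per_min: float
    modularity: float
    n_communities: int
    large_community_count: int
    ltu: Optional[float] = None
    freq_labeled: Optional[float] = None
    config: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def summary_row(self) -> dict:
        """The feature-table row: Top5PC Var (%), C_g, G_g, LtU, Freq.,
        Freq. labeled."""
        return {
            "Top5PC Var (%)": self.top5pc_var_percent,
            "C_g": self.clustering_coeff,
            "G_g": self.global_efficiency,
            "LtU": self.ltu,
            "Freq.": self.freq_events_per_min,
            "Freq. labeled": self.freq_labeled,
        }


def _write_matrix_csv(path: Path, values: np.ndarray, ids: list[str]) -> None:
    df = pd.DataFrame(values, index=ids)
    df.index.name = "Cell"
    df.to_csv(path)


def run_pipeline(
    traces_path: str | Path,
    cells_path: str | Path,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineReport:
    """Execute every stage in order and return the summary report.

    When ``out_dir`` is given, all intermediates, the report JSON and a
    manifest are written there; on a stage failure the manifest records
    the completed stages and the error, and the exception is re-raised
    with the stage name in the message.
    """
    cfg = config or PipelineConfig()
    outp: Optional[Path] = None
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    completed: list[str] = []
    stage = "load"

    def _art(name: str, fname: str) -> Path:
        assert outp is not None
        p = outp / fname
        artifacts[name] = str(p)
        return p

    try:
        traces = core_io.read_traces(
            traces_path, cfg.frame_interval_s, transpose=cfg.transpose_traces
        )
        cells = core_io.align_cells(traces, core_io.read_cells(cells_path))
        log.info(
            "load: %d cells x %d frames at %.3g s/frame",
            traces.n_cells, traces.n_time, cfg.frame_interval_s,
        )
        completed.append(stage)

        stage = "normalize"
        if cfg.normalization_method == "minmax":
            norm = preprocess.normalize_minmax(traces)
        elif cfg.normalization_method == "zscore":
            norm = preprocess.normalize_zscore(traces)
        else:
            raise ValueError(
                f"unknown normalization {cfg.normalization_method!r}"
            )
        if outp:
            _write_matrix_csv(
                _art("normalized", "normalized.csv"), norm.values, norm.cell_ids
            )
        completed.append(stage)

        stage = "binarize"
        raster = preprocess.binarize(norm, k=cfg.binarize_k)
        if outp:
            _write_matrix_csv(
                _art("raster", "raster.csv"), raster.values, raster.cell_ids
            )
        completed.append(stage)

        stage = "population"
        activity = population.active_percentage(raster)
        freq = population.events_per_min(raster, mode=cfg.events_mode)
        order = population.cluster_traces(
            norm, linkage=cfg.cluster_linkage, metric=cfg.cluster_metric
        )
        if outp:
            pd.DataFrame(
                {
                    "time_s": activity.time_s,
                    "percent_active": activity.percent_active,
                }
            ).to_csv(_art("activity", "activity.csv"), index=False)
            pd.DataFrame(
                {
                    "position": np.arange(len(order.ordering)),
                    "Cell": [norm.cell_ids[i] for i in order.ordering],
                }
            ).to_csv(_art("raster_order", "raster_order.csv"), index=False)
        completed.append(stage)

        stage = "connectivity"
        source = raster if cfg.connectivity_source == "binarized" else norm
        if cfg.connectivity_source not in ("binarized", "normalized"):
            raise ValueError(
                f"unknown connectivity source {cfg.connectivity_source!r}"
            )
        cmat = conn.connectivity_matrix(source, lag_max=cfg.connectivity_lag_max)
        if outp:
            _write_matrix_csv(
                _art("connectivity", "connectivity.csv"),
                cmat.rho_max,
                cmat.cell_ids,
            )
        completed.append(stage)

        stage = "graph"
        graph = gm.build_graph(cmat, theta=cfg.network_threshold, cells=cells)
        completed.append(stage)

        stage = "metrics"
        degs = gm.degree_stats(graph)
        cg = gm.clustering_coefficient(
            graph, count_low_degree_as_zero=cfg.clustering_count_zero
        )
        gg = gm.global_efficiency(graph)
        part = gm.detect_communities(graph)
        if outp:
            core_io.write_graph(graph, _art("graphml", "network.graphml"))
            core_io.write_graph(
                graph, _art("edges", "edges.csv"), format="edge_csv"
            )
            pd.DataFrame(
                {
                    "Cell": list(part.membership),
                    "community": list(part.membership.values()),
                }
            ).to_csv(_art("membership", "membership.csv"), index=False)
        completed.append(stage)

        stage = "subset"
        ltu = freq_labeled = None
        label = cfg.subset_label
        if label is None and cells.labels is not None:
            values = cells.label_values()
            if len(values) == 1:
                label = values[0]
            elif len(values) > 1:
                raise ValueError(
                    f"multiple label values {values}; set subset_label"
                )
        if label is not None:
            rep = subset_mod.subset_summary(
                graph, raster, label, events_mode=cfg.events_mode
            )
            ltu = rep.ltu
            freq_labeled = rep.freq_labeled
        completed.append(stage)

        stage = "pca"
        pca = spectra.pca_traces(norm, orientation=cfg.pca_orientation)
        if outp:
            pd.DataFrame(
                {
                    "component": np.arange(1, pca.n_components + 1),
                    "explained_percent": 100.0 * pca.explained_ratio,
                }
            ).to_csv(_art("scree", "scree.csv"), index=False)
        completed.append(stage)

        stage = "psd"
        psd = spectra.welch_psd(
            norm,
            segment_len=cfg.psd_segment_len,
            overlap_frac=cfg.psd_overlap_frac,
            window=cfg.psd_window,
        )
        if outp:
            psd_df = pd.DataFrame(
                psd.power.T, columns=psd.cell_ids
            )
            psd_df.insert(0, "freq_hz", psd.freqs_hz)
            psd_df.to_csv(_art("psd", "psd.csv"), index=False)
        completed.append(stage)

        stage = "report"
        report = PipelineReport(
            n_cells=traces.n_cells,
            n_time=traces.n_time,
            top5pc_var_percent=pca.top5_percent,
            clustering_coeff=cg,
            global_efficiency=gg,
            mean_degree=degs.mean_degree,
            freq_events_per_min=freq,
            modularity=part.modularity,
            n_communities=part.n_communities,
            large_community_count=part.large_community_count,
            ltu=ltu,
            freq_labeled=freq_labeled,
            config=cfg.to_dict(),
            artifacts=artifacts,
        )
        if outp:
            report_path = _art("report", "report.json")
            report_path.write_text(report.to_json())
            (outp / "manifest.json").write_text(
                json.dumps(
                    {"complete": True, "stages": completed + ["report"],
                     "artifacts": artifacts},
                    indent=2,
                    sort_keys=True,
                )
            )
        completed.append(stage)
        return report
    except Exception as exc:
        if outp is not None:
            (outp / "manifest.json").write_text(
                json.dumps(
                    {
                        "complete": False,
                        "failed_stage": stage,
                        "error": str(exc),
                        "stages": completed,
                        "artifacts": artifacts,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
        raise PipelineError(f"[{stage}] {exc}") from exc


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def render_figures(
    out_dir: str | Path,
    dendrogram: bool = False,
    cell_id_mode: str = "communities",  # cell | communities
    node_labels: bool = False,
    formats: tuple[str, ...] = ("png", "svg"),
) -> dict[str, list[str]]:
    """Render the standard figures from a run directory's artifacts.

    Produces (a) the population-activity trace with the clustered raster,
    (b) the network drawn at the cells' spatial coordinates with
    community color/number coding, (c) the scree plot with the
    five-component marker, (d) the per-cell PSD.  Raises if a required
    artifact is missing, naming it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outp = Path(out_dir)

    def _need(fname: str) -> Path:
        p = outp / fname
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline artifact: {p}")
        return p

    written: dict[str, list[str]] = {}

    def _save(fig, stem: str) -> None:
        paths = []
        for ext in formats:
            p = outp / f"{stem}.{ext}"
            fig.savefig(p)
            paths.append(str(p))
        plt.close(fig)
        written[stem] = paths

    # (a) population activity + raster
    act = pd.read_csv(_need("activity.csv"))
    raster = pd.read_csv(_need("raster.csv"), index_col=0)
    order = pd.read_csv(_need("raster_order.csv"))
    ordered = raster.loc[[str(c) for c in order["Cell"]]]
    nrows = 3 if dendrogram else 2
    fig, axes = plt.subplots(
        nrows, 1, figsize=(8, 6 + 2 * dendrogram), sharex=False,
        gridspec_kw={"height_ratios": [1] * (nrows - 1) + [2]},
    )
    if dendrogram:
        from scipy.cluster import hierarchy as hc
        norm = pd.read_csv(_need("normalized.csv"), index_col=0)
        Z = hc.linkage(norm.to_numpy(), method="ward")
        hc.dendrogram(Z, ax=axes[0], no_labels=True, color_threshold=0)
        axes[0].set_title("Ward dendrogram")
    ax_act, ax_ras = axes[-2], axes[-1]
    ax_act.plot(act["time_s"], act["percent_active"], lw=0.8)
    ax_act.set_ylabel("% active cells")
    ax_act.set_xlabel("time (s)")
    ax_ras.imshow(ordered.to_numpy(), aspect="auto", cmap="Greys",
                  interpolation="nearest")
    ax_ras.set_ylabel("cells (cluster order)")
    ax_ras.set_xlabel("frame")
    fig.tight_layout()
    _save(fig, "population_activity")

    # (b) network at spatial coordinates
    import networkx as nx
    g = nx.read_graphml(_need("network.graphml"))
    pos = {
        n: (float(d.get("x", 0.0)), float(d.get("y", 0.0)))
        for n, d in g.nodes(data=True)
    }
    comm = {n: int(d.get("community", 0)) for n, d in g.nodes(data=True)}
    n_comm = len(set(comm.values()))
    fig, ax = plt.subplots(figsize=(7, 7))
    colors = [plt.cm.tab20(comm[n] % 20) for n in g.nodes]
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.3, width=0.5)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, node_size=60)
    if node_labels:
        if cell_id_mode == "cell":
            labels = {n: n for n in g.nodes}
        elif cell_id_mode == "communities":
            labels = {n: str(comm[n]) for n in g.nodes}
        else:
            raise ValueError(f"unknown cell_id_mode {cell_id_mode!r}")
        nx.draw_networkx_labels(g, pos, labels, ax=ax, font_size=6)
    ax.set_title(f"functional network ({n_comm} communities)")
    ax.set_aspect("equal")
    _save(fig, "network")

    # (c) scree
    scree = pd.read_csv(_need("scree.csv"))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(scree["component"], scree["explained_percent"], "o-", ms=3)
    ax.axvline(5, color="red", lw=1)
    ax.set_xlabel("principal component")
    ax.set_ylabel("% variance explained")
    fig.tight_layout()
    _save(fig, "scree")

    # (d) PSD
    psd = pd.read_csv(_need("psd.csv"))
    fig, ax = plt.subplots(figsize=(6, 4))
    freqs = psd["freq_hz"]
    for col in psd.columns[1:]:
        ax.plot(freqs, psd[col], lw=0.4, alpha=0.4, color="C0")
    ax.plot(freqs, psd.iloc[:, 1:].mean(axis=1), lw=1.5, color="C1",
            label="mean")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power / Hz")
    ax.legend()
    fig.tight_layout()
    _save(fig, "psd")

    return written
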