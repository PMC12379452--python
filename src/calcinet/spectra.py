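"""PCA of the trace matrix and per-cell Welch power spectral density.

PCA treats the traces matrix exactly as handed over: the cells-by-time
matrix makes cells the observations and time points the variables, which
are centered but not rescaled (the classical prcomp-style default).  The
headline summary is the percentage of variance captured by the top five
principal components — low-dimensional, synchronized populations
concentrate variance in few components, while desynchronized ones spread
it out.  ``orientation="time"`` transposes the analysis for users who want
time points as observations; the two are not equivalent and the default is
the documented convention.

The PSD uses Welch's method (averaged modified periodograms over
overlapping Hann-windowed segments), one spectrum per cell, with the
sampling rate derived from the frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import NormalizedTraces

__all__ = ["PCAResult", "PSDResult", "pca_traces", "welch_psd"]


@dataclass
class PCAResult:
    """Explained-variance fractions per component (descending) and the
    percentage captured by the first min(5, n_components) of them."""

    explained_ratio: np.ndarray
    top5_percent: float
    n_components: int

    @property
    def used_components(self) -> int:
        return min(5, self.n_components)


@dataclass
class PSDResult:
    freqs_hz: np.ndarray
    power: np.ndarray  # (n_cells, n_freqs)
    cell_ids: list[str]


def pca_traces(n: NormalizedTraces, orientation: str = "cells") -> PCAResult:
    """PCA of the traces with cells as observations (default).

    The number of retained components is min(n_obs - 1, n_vars); their
    explained-variance ratios are computed from the singular values of
    the column-centered matrix and sum to 1.
    """
    if orientation == "cells":
        X = np.asarray(n.values, dtype=float)
    elif orientation == "time":
        X = np.asarray(n.values, dtype=float).T
    else:
        raise ValueError(f"unknown PCA orientation {orientation!r}")
    n_obs, n_vars = X.shape
    if n_obs < 2:
        raise ValueError("PCA needs at least 2 observations")
    Xc = X - X.mean(axis=0, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    n_comp = min(n_obs - 1, n_vars)
    var = s[:n_comp] ** 2
    total = var.sum()
    if total == 0:
        # all observations identical: no variance to explain
        ratio = np.zeros(n_comp)
        top5 = 0.0
    else:
        ratio = var / total
        top5 = 100.0 * float(ratio[: min(5, n_comp)].sum())
    return PCAResult(
        explained_ratio=ratio, top5_percent=top5, n_components=n_comp
    )


def welch_psd(
    n: NormalizedTraces,
    frame_interval_s: float | None = None,
    segment_len: int | None = None,
    overlap_frac: float = 0.5,
    window: str = "hann",
) -> PSDResult:
    """One-sided Welch PSD per cell (power per Hz).

    Defaults: segments of min(256, n_time) samples, 50% overlap, Hann
    window, constant detrend per segment; fs = 1/frame_interval_s.
    """
    if frame_interval_s is None:
        frame_interval_s = n.frame_interval_s
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    if segment_len is None:
        segment_len = min(256, n.n_time)
    if segment_len > n.n_time:
        raise ValueError(
            f"segment_len {segment_len} exceeds n_time {n.n_time}"
        )
    fs = 1.0 / frame_interval_s
    freqs, power = signal.welch(
        np.asarray(n.values, dtype=float),
        fs=fs,
        window=window,
        nperseg=segment_len,
        noverlap=int(overlap_frac * segment_len),
        axis=-1,
    )
    return PSDResult(
        freqs_hz=freqs, power=power, cell_ids=list(n.cell_ids)
    )
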