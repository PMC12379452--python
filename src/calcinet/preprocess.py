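"""Per-cell normalization and binarization of calcium traces.

Two normalizations are offered.  Min-max scaling maps each cell's trace to
[0, 1] using its own extrema, compensating for heterogeneous indicator
expression across cells; it is the pipeline default.  Z-scoring (center to
mean 0, scale to unit sample variance) is available as an alternative via
``normalization.method = zscore``.  The two are intentionally kept distinct
and never mixed.

Binarization marks a cell active at frame *t* when its normalized signal
strictly exceeds mean + k*sd of that cell's full recording (default k = 2,
sample standard deviation with denominator n-1).  A user-supplied per-cell
rule can replace the threshold entirely.
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional

import numpy as np

from .core_io import BinaryRaster, NormalizedTraces, TraceMatrix

__all__ = ["normalize_minmax", "normalize_zscore", "binarize"]

#: traces whose range is below this are treated as constant
_EPS = 1e-300


def normalize_minmax(t: TraceMatrix) -> NormalizedTraces:
    """Scale each cell's trace to [0, 1] by its own min and max.

    x'_t = (x_t - min(x)) / (max(x) - min(x)), per cell over the whole
    recording.  A constant trace has no range; it maps to all zeros and a
    warning is emitted (shape is preserved so downstream stages keep
    working; the cell simply carries no signal).
    """
    v = np.asarray(t.values, dtype=float)
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    rng = hi - lo
    flat = (rng <= _EPS).ravel()
    if flat.any():
        ids = [t.cell_ids[i] for i in np.flatnonzero(flat)]
        warnings.warn(
            f"constant trace(s) mapped to all zeros: {ids}", stacklevel=2
        )
    safe = np.where(rng <= _EPS, 1.0, rng)
    out = (v - lo) / safe
    out[flat, :] = 0.0
    return NormalizedTraces(
        values=out,
        cell_ids=list(t.cell_ids),
        frame_interval_s=t.frame_interval_s,
        method="minmax",
    )


def normalize_zscore(t: TraceMatrix) -> NormalizedTraces:
    """Center each cell's trace to mean 0 and scale to unit sample variance.

    Unlike min-max the output is unbounded.  A zero-variance trace cannot
    be scaled and raises an error naming the cell.
    """
    v = np.asarray(t.values, dtype=float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    dead = (sd <= _EPS).ravel()
    if dead.any():
        ids = [t.cell_ids[i] for i in np.flatnonzero(dead)]
        raise ValueError(f"zero-variance trace(s), cannot z-score: {ids}")
    return NormalizedTraces(
        values=(v - mu) / sd,
        cell_ids=list(t.cell_ids),
        frame_interval_s=t.frame_interval_s,
        method="zscore",
    )


def binarize(
    n: NormalizedTraces,
    k: float = 2.0,
    custom_rule: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> BinaryRaster:
    """Threshold each cell's trace into active (1) / inactive (0) states.

    Default rule: active at *t* iff x'_t > mean(x') + k * sd(x'), with the
    sample standard deviation (ddof=1) over the full recording and a
    strict inequality.  A cell with zero variance yields an all-zero row
    (warning).  ``custom_rule``, when given, receives one cell's trace and
    must return a boolean/0-1 vector of the same length; it replaces the
    threshold rule entirely.
    """
    v = np.asarray(n.values, dtype=float)
    if custom_rule is not None:
        rows = []
        for i in range(v.shape[0]):
            r = np.asarray(custom_rule(v[i]), dtype=bool)
            if r.shape != v[i].shape:
                raise ValueError(
                    f"custom rule returned shape {r.shape} for cell "
                    f"{n.cell_ids[i]!r}, expected {v[i].shape}"
                )
            rows.append(r)
        out = np.vstack(rows).astype(np.int8)
        spec = "custom rule"
    else:
        if k < 0:
            raise ValueError("k must be non-negative")
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=1, keepdims=True)
        silent = (sd <= _EPS).ravel()
        if silent.any():
            ids = [n.cell_ids[i] for i in np.flatnonzero(silent)]
            warnings.warn(
                f"zero-variance trace(s) binarized to all zeros: {ids}",
                stacklevel=2,
            )
        out = (v > mu + k * sd).astype(np.int8)
        out[silent, :] = 0
        spec = f"mean + {k:g}*sd (sample sd, strict >)"
    return BinaryRaster(
        values=out,
        cell_ids=list(n.cell_ids),
        frame_interval_s=n.frame_interval_s,
        threshold_spec=spec,
    )
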