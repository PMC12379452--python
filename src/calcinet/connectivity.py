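"""Lagged cross-correlation and the peak-correlation connectivity matrix.

Functional connectivity between two cells is the maximum absolute
cross-correlation over a small set of integer lags, rho_max =
max_{tau in Lag} |rho(tau)|, with Lag = {-lag_max, ..., +lag_max}
(default lag_max = 1, i.e. one frame of slack in either direction).

The cross-correlation follows the classical time-series estimator used by
R's ``ccf()``:

    rho(tau) = K(tau) / (sigma_x * sigma_y)
    K(tau)   = (1/T) * sum over valid t of (x(t+tau) - mu_x)(y(t) - mu_y)

where the means and standard deviations are taken over the *full* series
with 1/T (population) normalization and the lagged sum runs only over the
overlapping samples (no padding).  A consequence worth knowing: a perfect
copy of a signal shifted by one frame has rho at that lag slightly below 1,
because the overlap is T-1 samples while the normalization stays 1/T.

Constant (zero-variance) cells have no defined correlation; in the matrix
their rows/columns are set to 0 (effectively isolating them) with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import BinaryRaster, NormalizedTraces

__all__ = ["ConnectivityMatrix", "cross_correlation", "connectivity_matrix"]


@dataclass
class ConnectivityMatrix:
    """Symmetric peak-correlation matrix with the attaining lags.

    ``rho_max[i, j]`` in [0, 1] with unit diagonal; ``best_lag[i, j]`` is
    the lag tau at which |rho_ij(tau)| attains the maximum, tie-broken by
    smallest |tau| then negative before positive.  ``source`` records
    whether the input was the normalized or the binarized signal.
    """

    rho_max: np.ndarray
    best_lag: np.ndarray
    lag_set: np.ndarray
    cell_ids: list[str]
    source: str = "normalized"

    @property
    def n_cells(self) -> int:
        return self.rho_max.shape[0]


def _lag_order(lag_max: int) -> list[int]:
    """Lags ordered by the tie-break rule: |tau| ascending, negative first."""
    out = [0]
    for a in range(1, lag_max + 1):
        out.extend([-a, a])
    return out


def cross_correlation(
    x: np.ndarray, y: np.ndarray, lag_max: int
) -> np.ndarray:
    """rho(tau) for tau = -lag_max .. +lag_max (ascending).

    Both series must have equal length T >= 2, be non-constant, and
    lag_max must be smaller than T.  rho(tau) correlates x shifted
    forward by tau against y, so for tau > 0 the x series leads.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    T = x.size
    if T < 2:
        raise ValueError("series too short")
    if lag_max < 0 or lag_max >= T:
        raise ValueError(f"lag_max must be in [0, {T - 1}]")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).mean())
    sy = np.sqrt((yc**2).mean())
    if sx == 0 or sy == 0:
        raise ValueError("constant series has undefined correlation")
    out = np.empty(2 * lag_max + 1)
    for i, tau in enumerate(range(-lag_max, lag_max + 1)):
        if tau >= 0:
            k = float(xc[tau:] @ yc[: T - tau]) / T
        else:
            k = float(xc[: T + tau] @ yc[-tau:]) / T
        out[i] = k / (sx * sy)
    return out


def connectivity_matrix(
    traces: NormalizedTraces | BinaryRaster,
    lag_max: int = 1,
) -> ConnectivityMatrix:
    """All-pairs peak-correlation matrix over lags {-lag_max .. +lag_max}.

    Vectorized over cell pairs: one T-length matrix product per lag, so
    the cost is O(n_cells^2 * T * lag_max).  Symmetry is exact because
    rho_ij(tau) = rho_ji(-tau) and the lag window is symmetric.
    """
    v = np.asarray(traces.values, dtype=float)
    n, T = v.shape
    if n < 2:
        raise ValueError("connectivity needs at least 2 cells")
    if lag_max < 0 or lag_max >= T:
        raise ValueError(f"lag_max must be in [0, {T - 1}]")

    mu = v.mean(axis=1, keepdims=True)
    xc = v - mu
    sd = np.sqrt((xc**2).mean(axis=1))
    silent = sd == 0
    if silent.any():
        ids = [traces.cell_ids[i] for i in np.flatnonzero(silent)]
        warnings.warn(
            f"constant cell(s) isolated in connectivity matrix: {ids}",
            stacklevel=2,
        )
    sd_safe = np.where(silent, 1.0, sd)

    # R[tau][i, j] = rho_ij(tau) for tau >= 0; rho_ij(-tau) = R[tau][j, i]
    denom = np.outer(sd_safe, sd_safe)
    rho_pos = []
    for tau in range(0, lag_max + 1):
        if tau == 0:
            K = xc @ xc.T / T
        else:
            K = xc[:, tau:] @ xc[:, : T - tau].T / T
        rho_pos.append(K / denom)

    order = _lag_order(lag_max)
    # stack |rho(tau)| in tie-break order; first argmax wins
    stack = np.empty((len(order), n, n))
    for s, tau in enumerate(order):
        stack[s] = np.abs(rho_pos[tau]) if tau >= 0 else np.abs(
            rho_pos[-tau].T
        )
    best = np.argmax(stack, axis=0)
    rho_max = np.take_along_axis(stack, best[None], axis=0)[0]
    lag_arr = np.array(order)
    best_lag = lag_arr[best]

    rho_max[silent, :] = 0.0
    rho_max[:, silent] = 0.0
    best_lag[silent, :] = 0
    best_lag[:, silent] = 0
    np.fill_diagonal(rho_max, 1.0)
    np.fill_diagonal(best_lag, 0)
    # numerical guard: correlations can exceed 1 by float error only
    np.clip(rho_max, 0.0, 1.0, out=rho_max)

    source = "binarized" if isinstance(traces, BinaryRaster) else "normalized"
    return ConnectivityMatrix(
        rho_max=rho_max,
        best_lag=best_lag.astype(int),
        lag_set=np.arange(-lag_max, lag_max + 1),
        cell_ids=list(traces.cell_ids),
        source=source,
    )
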