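"""Synthetic calcium-imaging populations with known ground truth.

The generator emulates the data regime the pipeline targets: dozens to
hundreds of cells imaged for a few hundred frames at 0.5 Hz, organized in
a small number of co-active assemblies, with a labeled subset.  The model:

* each assembly carries a shared binary event train (Bernoulli per frame
  at ``event_rate_hz * frame_interval_s``); every event has a shared
  burst amplitude drawn uniformly from [0.5, 1.5], the same for all
  cells expressing it;
* a member cell expresses each of its assembly's events with probability
  ``within_coupling``; it also picks up events of *other* assemblies with
  probability ``cross_coupling`` (background crosstalk);
* per-cell spike trains are convolved with an exponential calcium kernel
  exp(-t / decay_s) (truncated at five decay constants);
* each trace gets a multiplicative per-cell gain drawn from
  ``amplitude_range`` — this deliberately exercises the per-cell
  normalization — plus additive Gaussian noise (``noise_sd``);
* a fraction ``labeled_fraction`` of cells is labeled.  Labeled cells can
  be decoupled from the rest of the network
  (``labeled_coupling_multiplier`` < 1 scales their expression
  probability of shared assembly events) and made hyper- or hypoactive:
  ``labeled_rate_multiplier`` sets their *total* event rate to multiplier
  times the typical member rate (within_coupling * event_rate_hz), topped
  up with a private, uncoupled event train;
* same-assembly cells are placed in spatial blobs around assembly centers.

Everything is drawn from a single seeded generator, so a spec + seed pair
reproduces the dataset bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import CellTable, TraceMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Defaults emulate a control-like population: 60 cells in 3 assemblies,
    450 frames at 0.5 Hz (15 min), shared events at 0.05 Hz (~3 per
    minute), strong within-assembly coupling (0.9), weak crosstalk (0.02),
    a slow nuclear-indicator decay of 4 s, moderate noise, and a 15%
    labeled subset behaving like everyone else.
    """

    n_cells: int = 60
    n_time: int = 450
    frame_interval_s: float = 2.0
    n_assemblies: int = 3
    event_rate_hz: float = 0.05
    within_coupling: float = 0.9
    cross_coupling: float = 0.02
    decay_s: float = 1.5
    noise_sd: float = 0.05
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    labeled_fraction: float = 0.15
    labeled_rate_multiplier: float = 1.0
    labeled_coupling_multiplier: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        def _req(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ValueError(f"invalid SyntheticSpec.{name}: {why}")

        _req(self.n_cells >= 1, "n_cells", "must be >= 1")
        _req(self.n_time >= 2, "n_time", "must be >= 2")
        _req(self.frame_interval_s > 0, "frame_interval_s", "must be > 0")
        _req(
            1 <= self.n_assemblies <= self.n_cells,
            "n_assemblies",
            "must be in [1, n_cells]",
        )
        _req(self.event_rate_hz >= 0, "event_rate_hz", "must be >= 0")
        p = self.event_rate_hz * self.frame_interval_s
        _req(p <= 1, "event_rate_hz", "rate*frame_interval must be <= 1")
        _req(
            0 <= self.within_coupling <= 1, "within_coupling", "not in [0,1]"
        )
        _req(0 <= self.cross_coupling <= 1, "cross_coupling", "not in [0,1]")
        _req(self.decay_s > 0, "decay_s", "must be > 0")
        _req(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        lo, hi = self.amplitude_range
        _req(0 < lo <= hi, "amplitude_range", "need 0 < low <= high")
        _req(
            0 <= self.labeled_fraction <= 1,
            "labeled_fraction",
            "not in [0,1]",
        )
        _req(
            self.labeled_rate_multiplier >= 0,
            "labeled_rate_multiplier",
            "must be >= 0",
        )
        _req(
            0 <= self.labeled_coupling_multiplier <= 1
            or self.labeled_coupling_multiplier >= 0,
            "labeled_coupling_multiplier",
            "must be >= 0",
        )


@dataclass
class GroundTruth:
    """What the generator knows: assembly membership, label indicator,
    the shared event frames per assembly, and the same-assembly pair
    indicator matrix."""

    assembly_of: np.ndarray
    labeled: np.ndarray
    event_times: list[np.ndarray]
    true_pair_coupled: np.ndarray


def _calcium_kernel(decay_s: float, frame_interval_s: float) -> np.ndarray:
    n = max(1, int(np.ceil(5.0 * decay_s / frame_interval_s)) + 1)
    t = np.arange(n) * frame_interval_s
    return np.exp(-t / decay_s)


def generate(spec: SyntheticSpec) -> tuple[TraceMatrix, CellTable, GroundTruth]:
    """Draw one synthetic recording (traces, coordinates+labels, truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, T, A = spec.n_cells, spec.n_time, spec.n_assemblies

    # round-robin assembly assignment keeps sizes balanced
    assembly_of = np.arange(n) % A
    labeled = np.zeros(n, dtype=bool)
    n_lab = int(round(spec.labeled_fraction * n))
    if n_lab:
        labeled[rng.choice(n, size=n_lab, replace=False)] = True

    p_event = spec.event_rate_hz * spec.frame_interval_s
    events = rng.random((A, T)) < p_event  # shared trains
    # burst size is a property of the population event, shared by every
    # cell that expresses it (keeps fully coupled cells identical)
    event_amp = rng.uniform(0.5, 1.5, size=(A, T))
    event_times = [np.flatnonzero(events[a]) for a in range(A)]

    spikes = np.zeros((n, T), dtype=float)
    for i in range(n):
        couple = spec.labeled_coupling_multiplier if labeled[i] else 1.0
        for a in range(A):
            p_expr = (
                spec.within_coupling
                if a == assembly_of[i]
                else spec.cross_coupling
            )
            p_expr = min(1.0, p_expr * couple)
            expressed = events[a] & (rng.random(T) < p_expr)
            spikes[i] += expressed * event_amp[a]
        if labeled[i] and spec.labeled_rate_multiplier != 1.0:
            # top up with private events so the labeled cell's total event
            # rate is multiplier x the typical member rate, regardless of
            # how strongly it is coupled to the shared events
            member_rate = spec.within_coupling * spec.event_rate_hz
            extra_hz = (
                spec.labeled_rate_multiplier - couple
            ) * member_rate
            extra_p = max(0.0, extra_hz * spec.frame_interval_s)
            private = rng.random(T) < min(1.0, extra_p)
            spikes[i] += private * rng.uniform(0.5, 1.5, size=T)

    kernel = _calcium_kernel(spec.decay_s, spec.frame_interval_s)
    calcium = np.apply_along_axis(
        lambda s: np.convolve(s, kernel)[:T], 1, spikes
    )

    gain = rng.uniform(*spec.amplitude_range, size=(n, 1))
    noise = rng.normal(0.0, spec.noise_sd, size=(n, T))
    traces = gain * calcium + noise

    # spatial blobs per assembly
    angles = 2.0 * np.pi * np.arange(A) / A
    centers = 100.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    xy = centers[assembly_of] + rng.normal(0.0, 10.0, size=(n, 2))

    ids = [f"cell{i}" for i in range(n)]
    cells = CellTable(
        x=xy[:, 0],
        y=xy[:, 1],
        cell_ids=ids,
        labels=["RFP" if l else None for l in labeled],
    )
    truth = GroundTruth(
        assembly_of=assembly_of,
        labeled=labeled,
        event_times=event_times,
        true_pair_coupled=(
            assembly_of[:, None] == assembly_of[None, :]
        ).astype(int),
    )
    tm = TraceMatrix(traces, ids, spec.frame_interval_s)
    return tm, cells, truth
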