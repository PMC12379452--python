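# Methods

This note documents the analytical conventions `calcinet` implements, the
choices that were genuinely open, and what the synthetic validation does
and does not demonstrate.

## Input model

The unit of analysis is one recording: an `n_cells × n_time` matrix of
fluorescence values (rows = cells, columns = frames) plus a coordinates
table (`X`, `Y`, `Cell`, optional `Label`). The frame interval in seconds
is a required explicit input — event rates and spectra are meaningless
without it; typical acquisitions here are 2 s/frame (0.5 Hz) or
0.5 s/frame (2 Hz). Traces are assumed complete: missing values are
rejected with the offending cell named, never imputed. Header rows and
leading id columns in the traces CSV are auto-detected (a first row with
any non-numeric non-leading field is a header; a first column with any
non-numeric body value is the id column, otherwise ids are the 0-based
row index), and `transpose` handles time-in-rows exports. Cell ids are
matched as whitespace-trimmed strings so numeric and string ids from
different export tools align.

## Preprocessing

**Min-max normalization** (default) maps each cell's trace to [0, 1]
using its own extrema. It compensates for heterogeneous indicator
expression across cells, at the price of sensitivity to outliers. A
constant trace has no range; it maps to all zeros with a warning rather
than NaN so downstream matrix shapes survive. **Z-scoring** (mean 0, unit
sample variance per cell) is available as `normalization.method =
zscore`; both are kept because either convention circulates in practice,
and they are deliberately not mixed or reconciled.

**Binarization** marks a cell active at frame *t* when its normalized
value strictly exceeds `mean + k·σ` over the full recording, `k = 2` by
default. σ is the *sample* standard deviation (denominator n−1) — the
default of the surrounding statistical ecosystem — and the inequality is
strict, so values exactly at the threshold are inactive. Because the
threshold co-varies with the trace's own mean and σ, binarization is
invariant to per-cell affine rescaling, and raising `k` can only ever
remove active samples. A user-supplied per-cell rule can replace the
threshold entirely.

## Population activity

The activity trace is the percent of cells active per frame. An **event**
is a rising edge (0→1 transition) of the binary trace, with a 1 in the
first frame counting as an onset; rates are onsets divided by duration,
with duration defined as `n_time × frame_interval_s` (not n−1 intervals).
This is the simplest convention consistent with counting discrete calcium
transients on a binary raster; `events.mode = frames` instead counts
active-frame occupancy for users whose definition is dwell time, without
any claim of equivalence. Raster rows are ordered by the dendrogram leaf
order of agglomerative clustering on the normalized traces (Ward linkage
on Euclidean distances by default; complete/average/single available).
Ward favours compact, homogeneous clusters — an assumption, not a fact
about the data — which is why the linkage is selectable.

## Connectivity

For cells *i, j* the lagged cross-correlation is

    ρ_ij(τ) = K_ij(τ) / (σ_i σ_j),
    K_ij(τ) = (1/T) Σ_valid t (x_i(t+τ) − μ_i)(x_j(t) − μ_j)

with means and σ over the **full** series, population (1/T)
normalization, and lag sums truncated to the overlapping samples (no
padding). This is the classical time-series estimator; one visible
consequence is that a perfect copy shifted by one frame scores slightly
below 1 at its lag (overlap T−1, normalization 1/T), which the tests
expect. The edge weight is `ρ_max = max |ρ(τ)|` over the symmetric lag
window (default ±1 frame, giving one frame of temporal slack in either
direction). Ties in the attaining lag resolve to the smallest |τ|,
negative before positive, for deterministic reporting. The matrix is
exactly symmetric because ρ_ij(τ) = ρ_ji(−τ). Constant cells (σ = 0)
have undefined correlation; their rows/columns are zeroed with a warning,
isolating them. The all-pairs computation is one T-length matrix product
per lag — O(n²·T·lag_max), no approximation.

The pipeline feeds the **binarized** signals to the connectivity step by
default, with `connectivity.source = normalized` honoring the continuous
convention; both circulate in practice and neither is silently
privileged. Binarized sources are recommended in low-SNR settings, where
thresholding suppresses noise-driven covariance.

## Graph construction and metrics

Edges are kept where `ρ_max ≥ θ` (inclusive; default θ = 0.3; `none`
disables filtering; a stricter θ = 0.6 preset is provided). Isolated
nodes stay in the vertex set. All topological metrics are computed on
the **unweighted** thresholded topology — the formulas below are
binary-adjacency formulas, and weights are retained for display/export
only:

* degree `k_i` and mean degree `⟨k⟩ = 2|E|/N`;
* average clustering coefficient `C(g)`: mean over nodes of
  `2e_i/(k_i(k_i−1))`. Nodes with `k_i < 2` have an undefined local
  coefficient and are **excluded** from the average (the local-average
  convention of the standard graph libraries; the literal formula
  divides by zero there). `count_low_degree_as_zero` switches to the
  count-as-zero alternative;
* global efficiency `G(g) = (1/(N(N−1))) Σ_{i≠j} 1/d_ij` with hop-count
  shortest paths; unreachable pairs contribute **zero** rather than being
  dropped from the denominator. On fragmented networks this pushes G(g)
  toward small values — entirely expected;
* communities by Newman's leading-eigenvector method: recursive spectral
  bisection on the (generalized) modularity matrix, seeded per connected
  component, splitting only while the leading eigenvalue exceeds 1e−10
  and the modularity gain exceeds 1e−12. The eigensolver is a dense
  symmetric decomposition with a fixed sign convention (first
  above-tolerance component positive), making the partition fully
  deterministic. Reported modularity is always re-evaluated from the
  direct Q formula. A "large" community has more than five members.

## Subset analysis

Given a label value, the package reports the induced subgraph on labeled
cells (same θ, same weights) with its metrics, the labeled subset's event
rate, and

    LtU = (# edges with exactly one labeled endpoint)
          / (n_labeled × n_unlabeled)

— each undirected cross edge counted once, over all possible cross
pairs. Alternative denominators (e.g. excluding within-group pairs from
some total) are conceivable; the definition above is the literal
"realized over possible cross connections" reading and is the one
implemented. When the coordinates table carries more than one distinct
label value, the analysis label must be chosen explicitly.

## PCA and PSD

PCA consumes the matrix exactly as held: cells are observations, time
points are variables; variables are centered, not rescaled, and
`min(n_cells − 1, n_time)` components are retained. The headline number
is the percentage of variance in the first `min(5, n_components)`
components (the report uses fewer than 5 only when fewer exist).
Synchronized, low-dimensional populations concentrate variance in few
components. The orientation is a convention, not a mathematical
necessity: `pca.orientation = time` transposes the analysis, with no
claim the two are comparable. The PSD is Welch's method per cell:
segments of `min(256, n_time)` samples, 50 % overlap, Hann window,
constant detrend per segment, one-sided spectrum at `fs =
1/frame_interval_s`. The method choice is standard; the segment defaults
are package decisions balancing variance reduction against frequency
resolution at these recording lengths.

## Pipeline

Stages run in a fixed order (load → normalize → binarize → population →
connectivity → graph → metrics/communities → subset → PCA → PSD →
report), every intermediate is written as CSV/GraphML/JSON, and figures
are rendered from those artifacts, not from hidden state. Nothing in the
chain draws random numbers, so two runs on identical inputs are
byte-identical — asserted in the tests. A stage failure aborts with a
stage-tagged error and a manifest marking the run incomplete.

## Synthetic generator

The generator emulates the target regime — 60 cells in 3 assemblies, 450
frames at 0.5 Hz by default — as: shared per-assembly Bernoulli event
trains (0.05 Hz), per-event burst amplitudes drawn U(0.5, 1.5) and shared
by every cell expressing that event, membership expression with
probability 0.9, cross-assembly crosstalk 0.02, an exponential calcium
kernel with a 1.5 s decay constant (truncated at five decay constants;
GCaMP6s-like transients that resolve between 2 s frames), per-cell
multiplicative gain U(0.5, 2.0) — deliberately exercising the per-cell
normalization — and additive Gaussian noise (σ = 0.05). A labeled
fraction (default 15 %) can be decoupled from the shared events
(`labeled_coupling_multiplier` scales its expression probabilities) and
made hyper-/hypoactive: `labeled_rate_multiplier` sets its *total* event
rate to a multiple of the typical member rate, topped up with a private
uncoupled train. All draws come from one seeded generator; identical
spec + seed reproduces the dataset bitwise.

What it does **not** model: biophysical indicator kinetics and
saturation, photobleaching and slow drift, motion artifacts, correlated
(shared) noise, spatially structured background. Passing the recovery
tests therefore shows the chain is correct and sensitive under clean,
assembly-structured conditions — it does not guarantee performance on
recordings dominated by drift or shared noise, where baseline correction
(out of scope here) would be needed first.

Validation uses this generator at its defaults: community detection on
the pipeline's graph recovers the planted assemblies (median adjusted
Rand index over 20 seeds, threshold 0.9), and a perturbed fixture
(labeled rate multiplier 1.8, coupling multiplier 0.3) is required to
show the qualitative contrast — higher labeled event rate, lower LtU —
against its matched control in at least 18 of 20 paired seeds. The
problem sizes (60 cells, 450 frames, 20 seeds) are the package's chosen
validation scale: large enough for stable recovery statistics, small
enough to run everywhere.

## Known limitations

* No ΔF/F₀ baseline correction or detrending; traces are taken as given.
* No significance testing of correlations (no shuffle/surrogate nulls),
  no partial correlation, no directed inference.
* Metrics are unweighted by design; weighted clustering/efficiency
  variants are not provided.
* Group-level inferential statistics across samples are left to the
  user; the pipeline emits one summary row per recording for exactly
  that purpose.
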