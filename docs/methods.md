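# Methods

This note documents the models, conventions and defaults behind the
package; it states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Signal model and preprocessing

Recordings are channels × samples voltage blocks (µV), one per subject and
condition (eyes closed EC, eyes open EO).  Offline preprocessing is a
band-pass plus line-noise notch.  The filter family and order are not
dictated by the problem, so they are declared defaults: a 4th-order
Butterworth band-pass (0.5–70 Hz) and an IIR notch at 60 Hz (quality
factor 30), both applied forward–backward (`sosfiltfilt`/`filtfilt`).
Zero-phase filtering matters here: the downstream estimators are phase
statistics, and a causal filter's phase response would bias them.  The
narrow notch rings for a few hundred milliseconds at signal onset; edge
samples are additionally excluded by the wavelet validity mask below, and
tests that measure stop-band attenuation discard 2 s per edge.

## Time–frequency decomposition

Each channel is convolved with complex Morlet wavelets: a complex
exponential at centre frequency f tapered by a Gaussian of width
σ_t = n_cycles / (2πf).  Defaults: 7 cycles at every frequency (long
resting epochs favour frequency precision over time precision), support
−1 … +1 s sampled at fs (hence an odd kernel length, 2·fs + 1), unit-energy
normalisation.  The alpha band is 8–12 Hz inclusive in 1 Hz steps; a wider
default axis of 2–45 Hz is available (`default_frequencies`).  Convolution
is linear and same-length; at least half a kernel length at each edge is
masked rather than padded, so no padded samples ever enter a phase or
power statistic.  Connectivity is computed per frequency and averaged
across band frequencies — averaging complex signals across frequencies
first would change the phase statistics and is not offered.

## Connectivity estimators

* **Windowed Spearman power correlation.**  Power series are cut into
  non-overlapping 5 s windows; each window is rank-transformed (average
  ranks on ties) and Pearson-correlated; per-window coefficients are
  averaged.  A window in which either series is constant has no defined
  correlation: it is skipped and logged, and if fewer than half the
  windows survive the estimate is refused rather than silently degraded.
  Fisher-Z (atanh) is available for averaging/statistics but is never
  applied before thresholding or wiring-cost weighting.
* **ISPC** = |n⁻¹ Σ exp(i Δφ(t))| over the whole valid series (a windowed
  variant averaging the per-window ISPC exists behind a switch).
* **PLI** = |n⁻¹ Σ sgn(imag Sₓᵧ(t))| with Sₓᵧ(t) = zₓ(t)·z̄ᵧ(t), the
  instantaneous wavelet cross-spectrum — the natural choice given that
  phases come from the same wavelet convolution; no segment-averaged
  spectral estimator is involved.  sgn returns +1/−1/0, and imaginary
  parts below 1e−12·|S| are treated as exact zeros: analytically zero-lag
  samples otherwise pick up arbitrary float-rounding signs, which would
  destroy the estimator's defining insensitivity to zero-lag coupling.

All three estimators are symmetric, the matrix diagonal is fixed at 0 and
excluded from every statistic; ISPC/PLI lie in [0, 1], raw Spearman in
[−1, 1].

## Wiring cost

With electrode coordinates in Cartesian mm, D_ij is the straight-line
Euclidean distance (cortical-surface geodesics are out of scope) and the
wiring-cost matrix is the elementwise product W = D ∘ F.  The network
scalar is the sum of W_ij over unordered pairs carrying an edge (mean per
edge available as an alternative aggregate).  Anticorrelated pairs under
the Spearman measure keep their signed product — whether negative
"costs" are meaningful is genuinely open, so the fraction of negative
entries is logged rather than silently clipped.

## Fixed-threshold networks and metrics

The single-threshold network keeps an edge iff F_ij ≥ τ with
τ = mean + population SD (ddof = 0) of the upper-triangle values.  The
14-metric battery is computed on the binary graph; per-node quantities
(degree, centralities, matching index, topological overlap) are averaged
so each metric is one scalar per network.  Degenerate-graph conventions,
chosen so every value is finite: characteristic path length averages
geodesics over reachable pairs (0 if none; the unreachable-pair count is
reported alongside); assortativity and the core/periphery quality are 0
when their defining correlation is degenerate; eigenvector centrality is
computed on the largest component, zeros elsewhere, normalised to unit
maximum; community structure is the greedy modularity-maximising
partition and the reported scalar is its modularity Q; PageRank uses
damping 0.85 and tolerance 1e−9.  The core/periphery score is a
Borgatti–Everett-style Pearson correlation between the adjacency and an
ideal core/periphery pattern with a deterministic core (nodes of degree ≥
mean degree) — deliberate determinism over a combinatorial search.

Because implants differ across subjects, raw networks are not comparable;
the unit of comparison is always the within-subject EC − EO difference.

## Filtration

The threshold vector is the sorted multiset of the matrix's unique-pair
values (n(n−1)/2 of them; including the symmetric duplicates would induce
the identical network family).  Two rules coexist deliberately: the fixed
μ+σ network keeps *strong* edges (superlevel), while the filtration
default is *sublevel* (edge iff value ≤ τ) so the family is monotone —
empty below the minimum, complete at the maximum — and the per-threshold
curves are right-continuous step functions.  Curves track density, mean
clustering, characteristic path length and the wiring cost of surviving
edges, computed with array/`csgraph` routines for speed; a test
cross-checks them against the independent graph-library route.  Condition
difference curves are formed by re-evaluating both step functions on the
sorted union of the two threshold grids and subtracting; at the final
grid point both families are complete, so density and clustering
differences end at exactly zero.

The sweep can run on the connectivity matrix F or on the wiring-cost
matrix W.  **W is the default**, for a substantive reason found during
development: the area statistic of the curve test integrates |EC − EO|
over the threshold grid, and on the F scale the entire between-condition
wiring-cost contrast sits at the grid's final point (the complete-graph
plateau), where it contributes nothing to the integral — the test's power
against the built-in contrast drops to roughly 60%.  On the W scale the
contrast spreads across the grid and the same test rejects essentially
always.  Both options remain exposed (`filtrate_on`) and are recorded in
every output.

## Permutation statistics

The exchangeability unit is the 5 s analysis window; under the null of no
condition effect, windows are exchangeable between the EC and EO
recordings of one subject (recorded minutes apart; no within-subject
variance model is assumed).

* **Channel test** — per window, each channel is summarised by its mean
  connectivity to all other channels; the statistic is the difference of
  condition means; the two-sided p-value comes from shuffling condition
  labels across pooled windows (default 10,000 permutations;
  p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm), resolution 1/(n_perm+1)).
  Per-region reporting surfaces each region's most significant channel.
* **Curve test** — the statistic is the trapezoidal area between the two
  condition filtration curves on the union grid, one per tracked metric;
  each permutation reassigns windows, re-averages the window-level
  connectivity matrices, re-runs both filtrations and re-measures the
  area (one-sided: large areas are extreme).

The choice of a permutation construction (rather than, e.g., a t-test)
is deliberate: it is distribution-free, exact at its resolution, and its
calibration is itself verified by simulation in the acceptance tests
(type-I error 0.05 within the stated bands).  Benjamini–Hochberg FDR
across channels is available but off by default, matching per-channel
uncorrected reporting conventions.  Star coding: `*` p < 0.05, `**`
p < 0.001.

## Synthetic cohort generator

The generator emulates what the analysis assumes about this class of
recordings, not the biophysics.  Per condition: a latent driver
oscillator at the band centre (10 Hz) with a slowly drifting phase
(0.5 rad/√s) and a smooth log-normal amplitude envelope (≈0.5 s
timescale, 0.4 log-SD); each channel mixes the driver (weight √g_i, with
g_i the channel's maximum coupling-matrix entry) with a private oscillator
of the same form but fast phase drift (6 rad/√s), adds a fixed per-channel
phase lag (0.15–0.6 rad, random sign — so coupling is never zero-lag and
PLI can detect it), scales by √(alpha_power_scale), and adds 1/f^β noise
(β = 1, RMS 10 µV against a 20 µV alpha amplitude).  Defaults are the
study conditions: 3-minute conditions, 500 Hz sampling (unstated in the
study design, declared not inferred), EC coupling 0.8 / power scale 1.0
versus EO coupling 0.2 / power scale 0.5 — the alpha-desynchronization
direction.  One master seed expands to per-subject child seeds by fixed
arithmetic and to per-condition child streams, so cohorts are
reproducible piecewise; layouts (grids, strips, depths; 10 mm spacing)
cycle through clinical implant archetypes, every subject with at least
one depth array.

What the generator does *not* emulate — volume conduction, a common
reference, non-stationary artifacts, heterogeneous per-pair coupling
within a condition, seizure activity: passing tests therefore demonstrate
the pipeline's correctness and sensitivity under its own assumptions, not
performance on clinical recordings.

## Problem sizes and numerical conventions

The test suite and acceptance script use scaled-down problem sizes chosen
as the package's own defaults for desk-scale verification: cohort runs at
250 Hz with 6–13 channels, effect-detection and calibration at 60–180 s
per condition, permutation counts 99–199 where the full default is
10,000, and the exhaustive graph-metric check enumerates all 1,024
5-node graphs.  Matrices are written with 12 significant digits, so
write/read round-trips are lossless at 1e−12.  EDF export quantises to
16 bits of the per-channel range (relative error ≈ 2e−5), which is why
byte-identity is asserted on numeric tables and not claimed across an
EDF round-trip.

## Known limitations

* The EC→EO recording order is fixed, as in the study design this
  emulates; order effects are confounded with condition.
* The wiring-cost scalar for a thresholded network is a design choice
  (off-diagonal half-sum over surviving edges); other aggregations are
  plausible and one (mean per edge) is provided.
* Characteristic path length on disconnected graphs is a convention, not
  a definition; the unreachable-pair count should be read alongside it.
* The per-channel test construction (mean connectivity to all others,
  window permutation) is one reasonable operationalisation of a
  per-channel condition contrast, not a canonical one.
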