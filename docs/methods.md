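# Methods

## Model and pipeline

The analysis treats a subject's conditioned component time courses as
piecewise-stationary multivariate Gaussian: at any time the R-channel
signal has one of a small number of covariance patterns ("connectivity
states"), and the whole-brain correlation matrix estimated in a short
sliding window is a noisy observation of the active state's matrix (a
mixture of two states when the window straddles a transition). The
pipeline estimates the states by clustering windowed matrices, then
compares groups on how long they dwell in each state, on edge-level
differences within states, and on the composition of connection strengths.

### Time-course conditioning

Order is fixed: drop initial volumes → polynomial detrend → nuisance
regression → despike → low-pass filter → mean-center.

- `drop_volumes` (default 10): equilibration volumes removed before
  anything else; 180 acquired volumes at TR = 2 s leave 170 timepoints.
- Detrending removes a least-squares polynomial fit up to degree 3
  (linear, quadratic, cubic trends plus intercept), per region, on a time
  axis rescaled to [−1, 1] for conditioning.
- The six rigid-body realignment parameters (3 translations mm, 3
  rotations rad) plus an intercept are regressed out. Inside the full
  chain the regressors are first detrended with the same basis, so by
  Frisch–Waugh–Lovell the sequential residual is exactly the joint
  trend+motion regression residual (and exactly orthogonal to the
  combined design). A rank-deficient design falls back to the
  pseudoinverse with a warning.
- Despiking re-implements the standard AFNI-style soft compressor: a
  cubic baseline is fitted per region (matching the detrending order),
  the residual scale s is the Gaussian-scaled median absolute deviation,
  and residuals beyond c1·s are mapped to
  `s·(c1 + (c2−c1)·tanh((|r|/s − c1)/(c2−c1)))`, continuous at the
  threshold and bounded by c2·s. Defaults c1 = 2.5, c2 = 4. A region
  with zero MAD is returned unchanged.
- The low-pass filter is a zero-phase (forward–backward) 5th-order
  Butterworth with 0.15 Hz cutoff (Nyquist 0.25 Hz at TR = 2 s). The
  filter family and order are this package's choice; the cutoff is the
  protocol constant.

### Tapered window and weighted correlation

The taper is a rectangle of `width_tr` = 22 samples convolved with a
discrete Gaussian (σ = 3 samples, support ±⌈3σ⌉), truncated back to the
central 22 samples — keeping the nominal window width — and normalized to
sum 1. Windows slide in steps of 1 TR starting at offsets
0 .. T − width − 1, so T timepoints yield `T − width` windows (170 → 148);
the final timepoint is unused. This is the only start convention
consistent with all the protocol constants at once, and it is asserted as
a contract.

Within a window, taper weights define the weighted mean, variance and
covariance; correlations are their normalized ratio, clipped to [−1, 1].
A region with zero weighted variance in a window gets zero correlations
there (with a warning). Weighted correlation is invariant to positive
affine rescaling per region.

### Graphical-lasso regularization

Per subject, a single penalty λ is selected from an 8-point grid
(10^−3 … 10^0.5) by leave-one-out held-out log-likelihood over a subsample
of ≤ 20 evenly spaced windows: for each held-out window the model is the
graphical-lasso covariance fitted to the mean of the remaining subsampled
matrices, scored by `log det Θ − tr(S_held Θ)`. Penalties where the solver
fails (window matrices of width 22 are rank-deficient for R > 22, and the
coordinate-descent solver can fail at small λ) are dropped with a warning.
Every window is then refitted at the selected λ; outputs are positive
definite and precision sparsity is non-decreasing in λ. At λ = 0 the
penalized MLE given an empirical covariance is that covariance, so the
input is returned. Regularization is switchable: clustering can consume
either raw weighted correlations or the regularized matrices. At full
problem size (54 regions × 148 windows × many subjects) the per-window
solves dominate runtime, so the large validation studies in this
repository cluster the unregularized correlation series; the
regularization path is validated on smaller full-rank problems.

### State clustering (k-means under L1)

Windows from all subjects and both groups are pooled (shared states per
k) and vectorized as the upper triangle excluding the diagonal (the
diagonal is constant for correlation-scale matrices and would dilute
distances). The clustering is k-means with Manhattan distance made
internally consistent: assignment by minimal L1 distance, centroid update
by the element-wise median, which is the L1-optimal centroid (a mean
update with L1 assignment is available as a sensitivity switch).
Initialization is k-means++-style with selection probability proportional
to the L1 distance to the nearest chosen center. An empty cluster is
re-seeded at the point farthest (L1) from its assigned centroid.
Iteration stops when assignments are unchanged or at 300 iterations; the
best of `n_replicates` (protocol value 150) restarts by total L1 cost is
returned, deterministically under a seed (replicates draw from spawned
seed streams). Cluster-number diagnostics (elbow cost, Calinski–Harabasz
with L1 dispersions, gap statistic against 20 uniform bounding-box
references) are reported for the sweep but never auto-select k; the
analysis sweeps k = 2..20 as the protocol prescribes.

### Dwell, reliability, medoids

Mean dwell time (MDT) of subject i in state s is the mean length of
maximal consecutive runs of s in the subject's window-assignment
sequence; occupancy is the total window count. A subject that never
visits a state contributes no MDT and is excluded from that state's
group test. A state is *reliable* when it covers ≥ 10 windows in each
group (AND across groups); only reliable states enter group statistics.
A subject's "median covariance matrix" for a state is the L1 medoid of
the subject's windows assigned to the state, ties broken toward the
earliest window.

Because runs are right-censored by the end of the scan, the descriptive
MDT underestimates the generative mean dwell. For parameter recovery the
package also provides the censoring-aware estimator
occupancy / observed exits (the MLE of the mean for a memoryless dwell
process); note that on *estimated* state sequences spurious one-window
exits near transitions inflate the denominator, so group MDT ratios —
which share that bias across groups — are the more robust effect-size
readout and are what the recovery benchmark reports.

### Group statistics

All two-sample comparisons are pooled-variance Student t-tests
(df = n1 + n2 − 2, two-sided p), computable from raw samples or
(n, mean, SD) summaries; this is the convention that reproduces the
printed demographic table p-values from its printed summaries. MDT tests
are flagged at p < 0.05. Edge-wise tests on state medoids use
α = 0.001 uncorrected, with direction "increase" when the case-group
mean exceeds the control mean; edges recurring in ≥ 5 of the (k, state)
tests across the sweep become findings (majority direction, ties to the
largest |t|). No further multiple-comparison correction is applied —
fidelity to the α + recurrence scheme is deliberate and is a known
limitation. Medoid entries are tested untransformed (no Fisher z) by
default, with a config switch left to the caller.

Strength discretization: per group, the pooled absolute off-diagonal
entries of all window matrices give cutpoints mean ± SD; level 1
("weak") is |v| ≤ mean − SD, level 3 ("strong") is |v| > mean + SD, and
values exactly at a cutpoint belong to the lower level (closed-below).
Composition percentages per (k, state, group) are computed over the
member matrices of that group's windows in the state by default (a
centroid-based switch exists); they always sum to 1.

## Synthetic data

The generator emulates the assumed data-generating process, not the
scanner: per subject, a semi-Markov state sequence (geometric run lengths
with the configured mean; next state from a zero-diagonal row-stochastic
transition matrix, uniform by default; initial state uniform) and
conditionally independent draws `x_t ~ N(0, Σ_state)` plus isotropic
observation noise `noise_sd²·I`. Geometric dwells are deliberate: the
mean is then the single dwell parameter with a closed-form target.
State matrices are unit-diagonal with equicorrelated blocks (correlation
0.6) over a state-specific random permutation of regions — disjoint
blocks keep them positive definite by construction — mimicking
subnetwork block structure. Group effects: the case-like group's
designated state can have its mean dwell multiplied by `dwell_ratio` and
a fraction of its elevated blocks demoted to near-zero correlation
(0.02), raising its weak-edge fraction. With both effects off, the
groups are stochastically identical.

Defaults are the study conditions: 54 regions, 170 timepoints at TR = 2 s,
group sizes 44 and 31, base mean dwell 40 windows per state (the order of
magnitude sliding-window state analyses report), observation noise
SD 0.2 (0.05 in the "low-noise" recovery setting). Dwell means are stated
in windows and converted to timepoints 1:1, since the window advances one
TR per step. Ground-truth *window* labels take the state at
`start + (width−1)//2` — the lower central sample, which is the
convention aligned with the symmetric taper's center of mass, so the
true label and the window's dominant mixture component switch at the
same offset.

What the generator does **not** emulate: hemodynamic convolution
(optional and off by default — the pipeline consumes already-extracted
component time courses), scanner drift/motion/physiological artifacts
(the conditioning stages are validated on constructed signals instead),
spatial maps or the ICA step, temporal autocorrelation within a state,
and gradual state transitions (switches are instantaneous). Passing
recovery tests therefore demonstrates estimator correctness under the
assumed switching-Gaussian model, not robustness to everything real
fMRI contains.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] and symmetrized; zero-variance
  windows yield zero correlations with a warning rather than NaNs.
- Columns are mean-centered after conditioning (covariance downstream is
  mean-invariant; centering stabilizes numerics).
- Constant-strength matrix sets make mean ± SD cutpoints collapse; this
  raises a "degenerate thresholds" error (detected at a relative 1e-12
  tolerance) rather than returning an empty middle level.
- Zero pooled variance in a t-test returns t = 0, p = 1 when means agree
  and errors otherwise; constant edges are skipped in edge-wise tests.
- Medoid and assignment ties break toward the earliest index;
  aggregation direction ties break toward the largest |t|.
- All stochastic stages fan a single user seed into independent
  per-subject / per-replicate / per-k streams via seed sequences, so
  stages rerun in isolation reproduce exactly.

## Validation problem sizes

The test suite validates each operation against independent oracles
(explicit summation formulas, exhaustive partition search, brute-force
pairwise distances, hand-enumerated runs) at small sizes, and the full
chain on simulated studies sized to run comfortably on one CPU: the main
recovery study uses 50 subjects/group at full dimensionality (54 regions,
170 timepoints, 3 states, 20 clustering replicates), dwell-test
calibration uses sequence-level simulation (20 seeds for power at
dwell_ratio 2, 200 reduced-size seeds for the null rate), and the
edge-finding null calibration runs 100 reduced-scale pipelines
(12 regions, 8+8 subjects, k = 2..4). The acceptance script repeats these
at further reduced sizes. The `analysis/` drivers default to a
demonstration scale (34 subjects, k ≤ 6) with flags for the full printed
protocol (k = 2..20, 150 replicates, regularization on).

## Known limitations

- Windows straddling state transitions are genuinely ambiguous: their
  matrices are mixtures, and labeling them by the window center makes
  roughly the central ±3 TRs around each transition coin-flips for any
  clusterer. At mean dwell 40 windows and width 22 this caps pooled
  window-label agreement (ARI) near 0.9 even when the recovered states
  themselves are essentially exact; measured disagreement is confined to
  transition-adjacent windows (zero error beyond ±8 TRs).
- The descriptive MDT is biased low by end-of-scan censoring; group
  ratios partially cancel the bias but residual attenuation remains at
  long dwells.
- The edge-finding scheme's α + recurrence rule controls false findings
  empirically (null calibration: zero findings in ≥ 95% of runs) but has
  no analytic family-wise guarantee.
- Graphical-lasso regularization of rank-deficient 54-region window
  matrices is slow with the coordinate-descent solver and can fail at
  small penalties; failing penalties are dropped from the grid, and the
  large simulation studies cluster unregularized correlations.
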