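# Methods

`chronnet` implements a complete source-space functional-connectivity
reliability pipeline for band-limited multichannel time series, together
with a synthetic cohort generator that plants every quantity the pipeline
is supposed to recover. This note documents the models, the numerical
choices, the synthetic study conditions, and what the tests do and do not
establish about real data.

## Connectivity estimators

**iPLV.** For two narrowband signals with instantaneous phases
φ_k(t), φ_l(t) (analytic-signal construction), the imaginary phase-locking
value is

    iPLV = (1/T) | Im Σ_t exp(i (φ_k(t) − φ_l(t))) |.

Zero-lag (and π-lag) phase relations contribute nothing to the imaginary
part, so instantaneous mixing — the dominant artifact of source leakage —
is suppressed by construction. The all-pairs matrix is computed as a
single complex Gram product of the phasor matrix.

**CorEnv.** Envelope coupling is the Pearson correlation of the slow
amplitude envelopes of two band-limited signals after bivariate
orthogonalization: each signal is regressed on the other, the residual's
envelope (computed analytically, since the Hilbert transform is linear)
is correlated with the partner's envelope, and the two directed values are
averaged. A scalar multiple of a signal therefore has CorEnv exactly 0.
For windowed (dynamic) CorEnv the leakage regression is estimated once on
the full recording — leakage between two sources is a fixed geometric
property of the inverse projection, not a window-varying one — and
envelopes are optionally low-pass smoothed at 1/width Hz before windowed
correlation (`env_lowpass="auto"`; set `None` to disable).

**Filtering.** Band-limiting uses a 4th-order Butterworth filter applied
forward and backward (`sosfiltfilt`), i.e. zero phase distortion, which is
what the phase estimator requires. Windows are planned in cycles of a
reference frequency; the arithmetic band center is the default reference
(`band_low`/`band_high` are selectable) because "n cycles of the studied
frequency" does not by itself pick a reference inside a band. Window count
is `floor((T − width)/step) + 1` with starts at multiples of the step.

## Statistical edge filtering

The null for each edge comes from single-cut surrogates: a recording is
cut once at a random point within ±`cut_halfwidth` seconds of its midpoint
(default 10 s) and the two blocks are exchanged. This preserves the sample
multiset and almost all autocorrelation structure while destroying
cross-series alignment. Each surrogate draw rotates every series at its
own cut point. Cut points within a draw are drawn sequentially with a
minimum pairwise separation (up to 0.5 s, shrunk when many series must fit
in the cut window): without the separation, occasional draws rotate a
coupled pair at nearly the same point, the coupling survives, and single
extreme null values destroy the one-sided test (under BH-FDR at q ≤ 0.01 a
single surrogate above the observed value can permanently reject a true
edge). The separation must not come from a fixed slot grid — a grid
quantizes every pairwise rotation lag to multiples of the slot width, so
the surrogate values collapse onto a few dozen distinct lags and the
effective null sample size shrinks far below the number of draws,
inflating the extreme-tail rate of the one-sided p-values. Sequentially
rejected draws keep the lags continuously distributed. For very-low-
frequency bands the decorrelation time of the signal can exceed the
separation floor; raise `cut_halfwidth` (widening the cut window) in that
regime.

One-sided p-values are the proportion of surrogate values at or above the
observed value (plain proportion, ties counted, no +1 correction). For
CorEnv the test is one-sided on the signed value — large positive coupling
counts as significant; this choice is recorded here rather than inferred.
Benjamini–Hochberg FDR at q ≤ 0.01 (statsmodels) is applied independently
within each graph snapshot's edge set; non-significant edges are zeroed.

For dynamic graphs, the surrogate transform is applied to the full-length
recording (not per-segment), and each draw is evaluated on one
window-length segment (draw s uses window s mod n_windows). The null
therefore has the same estimation length — hence the same small-sample
bias — as the observed windowed values, while being computed once per
recording and shared across windows. A full-length null would be far too
narrow for windowed estimates and would declare every edge significant.

The default surrogate budget is 200 (1000 selectable); the end-to-end
reliability demonstrations use 100 per edge to keep a 20-recording cohort
run within minutes on one core.

## Topological filtering (OMST)

Orthogonal minimal spanning trees: round r extracts the maximum-weight
spanning tree over edges not yet selected ("minimal" on 1/w distances —
the tree is identical because the MST depends only on the edge ordering),
removes those edges, and repeats. After each round the cumulative
selection is scored by

    J = GE − Cost,

where GE is the global efficiency of the selection on 1/w distances and
Cost is the selected weight over the total weight of the input graph. The
prefix of rounds maximizing J is returned; it is always connected, spans
between n−1 and rounds·(n−1) edges, and is a union of edge-disjoint
spanning trees. MSTs are computed with `scipy.sparse.csgraph`; with
continuous weights ties are measure-zero, and scipy's deterministic edge
processing makes results reproducible. CorEnv graphs enter OMST by
magnitude (spanning-tree machinery needs nonnegative weights); the signed
values are retained through statistical filtering.

In the pipeline, a statistically filtered snapshot can in principle be
disconnected (small synthetic graphs, sparse truth); OMST and the
eigenspectrum features require connectivity, so the study driver falls
back to the unfiltered snapshot for topological filtering at such windows
and counts the fallbacks in the report (`omst_fallbacks_*`; zero under the
default study conditions).

## Graph metrics

All shortest paths map weight w to distance 1/w. Global efficiency is the
mean of 1/d_ij over ordered pairs (nodal terms reported too); local
efficiency of node i is the efficiency of the subgraph of i's neighbors
normalized by k_i(k_i − 1); strength is the row sum. Shortest-path passage
probabilities treat the row-normalized weight matrix P as a random walk:
with B_j equal to P with column j zeroed (absorption at j),

    π_ij = 1 − Σ_v [B_j^{L_ij}]_{iv},

the probability of reaching j within the shortest-path hop count L_ij.
Hops are counted along the minimal 1/w-distance path, with a vanishing
per-hop penalty added to the Dijkstra distances so ties break toward fewer
hops (keeping B^L a plain matrix power). The literature sometimes labels
this family of quantities a "mean first passage time"; the formula yields
a probability, and the implementation names it accordingly.

The graph diffusion distance between two graphs is

    d² = max_{t>0} ‖exp(−t L₁) − exp(−t L₂)‖_F²,   L = D − A,

with the heat kernels evaluated spectrally, t searched on 60 log-spaced
points in [10⁻³, 10] and refined by bounded scalar minimization around the
best grid point. The distance is nonnegative, symmetric, and zero on
identical Laplacians; the triangle inequality is not asserted. The
subjects × sessions distance matrix is projected to a common 2-D space by
classical (Torgerson) MDS — eigendecomposition of the double-centered
squared-distance matrix, deterministic, with the stress-1 loss reported.

## Microstates and chronnectomics

Each windowed, filtered graph snapshot is summarized by the ascending
eigenvalues of its Laplacian: a permutation-invariant, n-dimensional
descriptor (versus n(n−1)/2 for a vectorized graph) of the snapshot's
synchronizability structure. Spectra are pooled across subjects per
session and frequency band and quantized with the neural-gas algorithm:
for each sample, all k prototypes move toward it with step
ε(t)·exp(−rank/λ(t)); the neighborhood range λ decays 10 → 0.01 and the
step ε 0.5 → 0.005, both exponentially over 50 epochs (defaults exposed in
`NeuralGasParams`). Features are used unstandardized — post-OMST
eigenvalues share a common scale, and the scale itself carries state
information; a variance-standardization switch can be added upstream by
the caller.

The codebook size k is the smallest k whose reconstruction error

    E = 100 · ‖X − X̂‖_F / ‖X‖_F   (X̂: each row replaced by its prototype)

falls below 4%; the full E-vs-k curve is returned for plateau inspection.
Codebooks are fit per session; k is selected on session 1 and reused for
session 2 so per-state comparisons are well-defined, and session-2 states
are matched to session-1 states by the prototype permutation with minimal
total Euclidean distance before any per-state statistic is compared.

Nearest-prototype assignment yields a per-recording symbolic state
sequence, modeled as a first-order Markov chain. Chronnectomics are the
transition rate TR = (state changes)/(windows − 1), the occupancy vector
OC (fraction of windows per state, summing to 1), and the k×k
transition-probability matrix (row-normalized pair counts; unvisited
source states flagged). TR and OC are invariant to any consistent state
relabeling.

Test-retest reliability of any per-subject statistic is the Pearson
correlation between the session-1 and session-2 values across the cohort
(a Spearman switch exists); per-ROI reliability vectors are produced for
the nodal metrics. No multiple-testing correction is applied across
bands/metrics in the report — raw r and p are emitted with n. Window
width/step can be optimized by grid search (default 1–10 cycles × 0.5 and
0.1–2 cycles × 0.1; 380 points) maximizing TR reliability, re-running the
full dynamic pipeline, including re-clustering, per grid point; desk-scale
runs subsample the grid.

## Synthetic cohort: what is planted and why

The generator produces subjects × two sessions of band-limited ROI time
series in which every downstream quantity is planted:

- **Phase coupling.** A state is realized by a shared band-limited carrier
  mixed into each ROI after a per-ROI phase rotation, so the planted lag
  between ROIs i, j is θ_i − θ_j (always realizable by construction).
- **State geometry.** The default two states couple *all* ROIs through a
  star-shaped lag pattern: ROI 0 is the hub (offset 0) and the leaves form
  two tight offset clusters near π/2 and π/2 + π. Hub–leaf lags are strong
  (|sin| ≈ 1) and mutually distinct, so the maximum-weight spanning tree
  is the star, uniquely and stably; leaf–leaf lags are all ≈ 0 or ≈ π,
  invisible to iPLV, so the significant edge set is exactly the star in
  every window. States differ in coupling strength (0.95 vs 0.8 of signal
  variance), which scales the whole Laplacian spectrum — a planted
  signature that survives the permutation invariance of eigenspectrum
  features (two states that merely couple *different* node subsets of
  equal size are graph-isomorphic and spectrally indistinguishable).
- **Carrier envelopes.** Shared carriers are envelope-normalized by
  default (`stabilize_envelopes=True`): the Rayleigh fading of narrowband
  noise otherwise makes the planted coupling strength fluctuate window to
  window and dominates the microstate reconstruction error. Disable it to
  plant envelope-correlation states instead (the dedicated
  `generate_envelope_coupled_pair` fixture plants CorEnv ground truth with
  exactly controlled envelopes on orthogonalized carriers).
- **Dynamics.** States switch at 8-s dwell-segment boundaries following a
  subject-specific 2×2 Markov chain. Per-state dwell probabilities sweep
  0.05–0.97 across subjects, with the state-2 sweep cyclically shifted
  relative to state 1, planting decorrelated between-subject spreads in
  both transition rate and occupancy. Session 2 uses the subject's
  transition matrix perturbed by Gaussian noise of scale `session_jitter`
  (rows re-normalized); jitter 0 makes the sessions bit-identical (the
  sub-seed scheme collapses to session 1), so every test-retest statistic
  is exactly 1 — the degenerate anchor of the reliability scale.
- **Seeding.** One global seed expands to per-subject/session/band/purpose
  sub-seeds through `numpy` `SeedSequence` spawn keys, so generation is
  bit-reproducible and order-independent.

**Desk study conditions.** The default test cohort is 10 subjects × 2
sessions × 12 ROIs at 80 Hz in a single broad 8–24 Hz band, 800 s per
recording (100 dwell segments), analyzed with 3-s windows stepped by 1 s
(798 windows) and 100 surrogates per edge. These sizes were chosen once,
on design grounds: (i) the bandwidth–time product of a window
(≈ 48) matches the estimator precision available to high-frequency bands
of full-scale recordings, which is the regime in which window-level state
recovery is well-conditioned; (ii) 100 dwell segments keep the binomial
sampling noise of each recording's transition count well below the planted
between-subject spread, so the planted test-retest correlation is ≈ 0.96
and the pipeline's target of r ≥ 0.9 measures recovery, not luck; (iii) 12
ROIs keep the all-pairs and per-window OMST costs at a scale where the
full two-branch study runs in minutes on one core. The synthetic
recordings are longer than a typical resting-state session precisely
because the cohort and ROI count are much smaller.

**What passing tests show — and what they don't.** The synthetic cohort
demonstrates that the pipeline recovers planted lags, envelope
correlations, states, transition dynamics, and their test-retest
reliability under piecewise-stationary, low-rank (one carrier per state)
coupling with abrupt state switches and stationary noise. Real recordings
violate all of these in degree: coupling is not low-rank, states are not
crisply piecewise-stationary, artifacts are non-stationary, and volume
conduction produces dense zero-lag structure rather than none. Passing
here validates the machinery and its statistical calibration, not any
claim about effect sizes or reliability levels in real data.

## Degenerate inputs and edge handling

- All-zero signals, NaNs, length mismatches, non-symmetric or negative
  weight matrices, disconnected graphs where connectivity is required, and
  non-row-stochastic transition matrices are rejected with messages.
- Zero-variance residuals in CorEnv contribute 0 with a warning; negative
  voxel strengths in ROI aggregation are floored at 0 with a warning, and
  a region with no positive total strength is rejected.
- Zero-variance reliability vectors yield NaN r values, flagged with a
  warning and serialized as null.
- Nearest-prototype ties resolve to the lowest state index; empty states
  yield zero prototype graphs with a warning.

## Known limitations

- The voxel-to-ROI aggregation weights use signed Pearson correlations
  with negative strengths floored at zero; regions dominated by
  anti-correlated voxels are rejected rather than re-signed.
- Local efficiency is identically zero on spanning trees, so its
  test-retest reliability is undefined (NaN) when OMST selects one round;
  this is a property of the metric on tree graphs, not a pipeline failure.
- The per-window surrogate null reuses one distribution across windows; a
  per-window surrogate recomputation would cost n_windows times more and
  is not implemented.
- `optimize_window` re-clusters per grid point (faithful to the stated
  pipeline); the full 380-point sweep multiplies the dynamic-branch cost
  accordingly and is intended for subsampled grids at desk scale.
- Cross-frequency and directed estimators, HMM/MAR state models, and
  non-negative-matrix-factorization codebooks are out of scope.
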