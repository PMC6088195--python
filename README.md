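# chronnet

Test-retest reliability of static and dynamic functional connectivity for
band-limited source-space time series — from multichannel recordings to
statistically and topologically filtered connectivity graphs, to
functional-connectivity microstates and chronnectomics, to reliability
reports. Includes a synthetic two-session cohort generator in which every
recovered quantity is planted, so the whole pipeline is validated against
known ground truth.

## Who this is for

Electrophysiology groups (MEG/EEG source-space analyses) who want to know
whether the network statistics they report — nodal graph metrics from
static connectivity, or state-transition statistics from dynamic
connectivity — are stable across repeat scans of the same subjects, and
who need a tested, deterministic reference implementation of the pipeline
pieces: iPLV / orthogonalized envelope correlation, single-cut surrogate
edge testing with BH-FDR, orthogonal-MST topological filtering, graph
diffusion distance with a common MDS projection, Laplacian-eigenspectrum
microstates via neural-gas quantization, and Markov-chain chronnectomics.

## The model in brief

For each subject, session and frequency band, ROI time series are
band-limited (zero-phase Butterworth) and turned into connectivity graphs
with one of two estimators:

- **iPLV** = (1/T) |Im Σ_t e^{i(φ_k(t) − φ_l(t))}| — phase locking that is
  blind to zero-lag (leakage-like) coupling;
- **CorEnv** — Pearson correlation of amplitude envelopes after bivariate
  orthogonalization (each signal regressed on the other; residual
  envelopes correlated; directed values averaged).

Graphs are filtered statistically (single-cut surrogates → one-sided edge
p-values → Benjamini–Hochberg FDR at q ≤ 0.01, non-significant edges
zeroed) and topologically (orthogonal minimal spanning trees: edge-disjoint
maximum-weight spanning trees accumulated until J = GE − Cost is maximal).

*Static branch:* nodal global/local efficiency, strength, and
shortest-path passage probabilities π_ij = 1 − Σ_v [B_j^{L_ij}]_{iv};
graph-level similarity via the diffusion distance
d² = max_t ‖e^{−tL₁} − e^{−tL₂}‖_F², projected to 2-D by classical MDS.

*Dynamic branch:* sliding-window graph tensors; each windowed graph is
summarized by its Laplacian eigenvalue spectrum (L = D − A); pooled
spectra are quantized by the neural-gas algorithm into k microstate
prototypes (k = smallest with reconstruction error E < 4%); the resulting
symbolic state sequence is modeled as a first-order Markov chain, yielding
the transition rate TR = transitions/(windows − 1), the occupancy vector
OC, and the transition-probability matrix.

*Reliability:* for any per-subject statistic, the Pearson correlation
between session-1 and session-2 values across the cohort; per-ROI r
vectors for nodal metrics, scalars for chronnectomics. Window width/step
can be optimized by maximizing TR reliability over a cycles grid.

See `docs/methods.md` for the full model description, numerical choices,
and the synthetic study conditions.

## Worked example

```python
import chronnet as cn
from chronnet.pipeline import StudyConfig, run_study

# 4 subjects x 2 sessions, 8 ROIs, 160 s at 80 Hz, two planted
# global-synchrony states switching under subject-specific Markov chains
cfg = cn.desk_cohort_config(n_subjects=4, seed=7, duration=160.0, n_rois=8)
study = StudyConfig(cohort=cfg, window_samples=(240, 80), surrogates=None)
report, artifacts = run_study(study)

entry = report.results["wide"]["iplv"]
print(f"microstates: k = {entry['k']}, reconstruction error = "
      f"{entry['recon_error_pct']:.2f}%")
print(f"TR  test-retest r = {entry['tr_r']:.3f} (p = {entry['tr_p']:.2e})")
print(f"OC  test-retest r = {[round(v, 3) for v in entry['oc_r']]}")
```

prints

```
microstates: k = 2, reconstruction error = 3.06%
TR  test-retest r = 0.998 (p = 2.29e-03)
OC  test-retest r = [0.99, 0.99]
```

The planted cohort has two microstates, and the pipeline selects k = 2
with a 3% reconstruction error; the subject-specific switching dynamics
agree between the two sessions up to the planted jitter, so the
transition-rate and occupancy reliabilities are near 1. The same report
carries the static branch: per-ROI reliability of nodal metrics
(`entry["nodal_reliability_mean_r"]`, here 0.99 for efficiency and
strength) and the stress of the common 2-D projection of the
subjects × sessions diffusion-distance matrix
(`entry["mds_stress"]`, here 0.006).

The same pipeline is scriptable from a shell:

```bash
chronnet simulate --subjects 10 --seed 1 --out cohort.h5
chronnet static      --in cohort.h5 --estimator iplv --surrogates 200 --out derived/
chronnet dynamic     --in cohort.h5 --estimator iplv --out dynamic.json
chronnet reliability --in cohort.h5 --report report.json --seed 1
chronnet optimize-window --in cohort.h5 --out window.json
```

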