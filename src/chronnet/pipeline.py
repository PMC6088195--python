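"""End-to-end study driver: cohort -> graphs -> filtering -> microstates ->
chronnectomics -> test-retest reliability report.

The static branch estimates whole-recording graphs, filters them
statistically (surrogates + FDR) and topologically (OMST), computes nodal
metrics and their per-ROI reliability, and summarizes graph-level
similarity via the diffusion-distance matrix projected to a common 2-D
space.  The dynamic branch estimates windowed graph tensors, filters every
snapshot, reduces snapshots to Laplacian eigenspectra, clusters them into
microstates per session (pooled across subjects), and reports the
test-retest reliability of the transition rate and per-state occupancy.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

from .bands import BandSpec
from .chronnectomics import nodal_reliability, occupancy, test_retest, transition_rate
from .connectivity import (
    DynamicFCGraph,
    WindowPlan,
    WindowSpec,
    bandpass,
    dynamic_fcg,
    static_fcg,
    window_plan,
)
from .filtering import SurrogateScheme, omst, statistical_filter
from .metrics import gdd_matrix, is_connected, mds_embed, nodal_metrics, passage_probability
from .microstates import (
    NeuralGasParams,
    apply_state_permutation,
    assign_symbols,
    match_codebooks,
    neural_gas_fit,
    select_k,
    transition_matrix,
)
from .synthetic import CohortConfig, CohortStore, GroundTruth, generate_cohort

__all__ = [
    "StudyConfig",
    "ChronRecord",
    "ReliabilityReport",
    "OptimizationGrid",
    "run_study",
    "dynamic_branch",
    "optimize_window",
]


@dataclass
class StudyConfig:
    """Parameters of one reliability study run."""

    cohort: CohortConfig
    window: WindowSpec | None = None
    window_samples: tuple[int, int] | None = None  # (width, step) overrides cycles
    estimators: tuple[str, ...] = ("iplv",)
    surrogates: SurrogateScheme | None = None      # None disables statistical filtering
    fdr_q: float = 0.01
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    e_threshold: float = 4.0
    ng_params: NeuralGasParams = field(default_factory=NeuralGasParams)
    static_branch: bool = True
    mds_dim: int = 2

    def plan_for(self, n_samples: int, fs: float, band: BandSpec) -> WindowPlan:
        if self.window_samples is not None:
            width, step = self.window_samples
            return WindowPlan.from_samples(n_samples, width, step, fs)
        if self.window is None:
            raise ValueError("StudyConfig needs a WindowSpec or window_samples")
        return window_plan(n_samples, fs, self.window, band)


@dataclass
class ChronRecord:
    """Chronnectomics of one recording."""

    subject: int
    session: int
    band: str
    estimator: str
    tr: float
    oc: np.ndarray
    tp: np.ndarray


@dataclass
class ReliabilityReport:
    """Nested study results plus provenance.

    ``results[band][estimator]`` holds the dynamic chronnectomic
    reliability ('tr_r', 'oc_r', ...), the static per-ROI reliability
    vectors, and diagnostic counters.  Serialization is deterministic
    (sorted keys, no timestamps).
    """

    results: dict
    seed: int
    n_subjects: int

    def to_json(self, path=None) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return clean(o.tolist())
            if isinstance(o, (np.floating, np.integer)):
                o = o.item()
            if isinstance(o, float) and not np.isfinite(o):
                return None  # undefined statistics (e.g. zero-variance r)
            return o
        text = json.dumps(
            clean({"seed": self.seed, "n_subjects": self.n_subjects,
                   "results": self.results}),
            indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _topological(w: np.ndarray, fallback: np.ndarray) -> tuple[np.ndarray, bool]:
    """OMST of a statistically filtered snapshot, falling back to the raw
    snapshot when filtering disconnected it (possible on sparse synthetic
    graphs; see report counter)."""
    mag = np.abs(w)
    if is_connected(mag):
        return omst(mag).w_filtered, False
    return omst(np.abs(fallback)).w_filtered, True


def dynamic_branch(
    store: CohortStore,
    band: BandSpec,
    estimator: str,
    config: StudyConfig,
    seed: int = 0,
):
    """Dynamic pipeline for one band/estimator across the whole cohort.

    Returns a dict with per-recording symbolic sequences, chron records,
    reliability values, the session codebooks and diagnostics.
    """
    fs = store.fs
    subjects = store.subjects
    sessions = store.sessions
    feats: dict = {}
    fallbacks = 0
    plan = None
    for sub in subjects:
        for ses in sessions:
            x = store.get(sub, ses, band.name)
            xb = bandpass(x, band, fs)
            plan = config.plan_for(x.shape[0], fs, band)
            dfc = dynamic_fcg(xb, band, estimator, fs, plan=plan,
                              filter_input=False)
            raw_tensor = dfc.tensor.copy()
            if config.surrogates is not None:
                dfc, _ = statistical_filter(dfc, xb, fs, config.surrogates,
                                            q=config.fdr_q)
            from .microstates import eigen_features
            filt = np.empty_like(dfc.tensor)
            for wi in range(dfc.n_windows):
                filt[wi], fb = _topological(dfc.tensor[wi], raw_tensor[wi])
                fallbacks += int(fb)
            feats[(sub, ses)] = eigen_features(filt, subject=sub, session=ses,
                                               band=band.name).x
    # pooled-per-session clustering
    pooled = {ses: np.vstack([feats[(sub, ses)] for sub in subjects])
              for ses in sessions}
    s1, s2 = sessions[0], sessions[-1]
    k, cb1, e_curve = select_k(pooled[s1], k_range=config.k_range,
                               e_threshold=config.e_threshold,
                               params=config.ng_params, seed=seed)
    cb2 = neural_gas_fit(pooled[s2], k, params=config.ng_params, seed=seed + k)
    perm = match_codebooks(cb1, cb2)

    n_win = next(iter(feats.values())).shape[0]
    records: list[ChronRecord] = []
    seqs: dict = {}
    for ses, cb in ((s1, cb1), (s2, cb2)):
        for si, sub in enumerate(subjects):
            f = feats[(sub, ses)]
            seq = assign_symbols(f, cb, subject=sub, session=ses, band=band.name)
            labels = seq.labels
            if ses == s2:
                labels = apply_state_permutation(labels, perm)
            seqs[(sub, ses)] = labels
            records.append(ChronRecord(
                subject=sub, session=ses, band=band.name, estimator=estimator,
                tr=transition_rate(labels), oc=occupancy(labels, k),
                tp=transition_matrix(labels, k).tp))

    tr1 = np.array([r.tr for r in records if r.session == s1])
    tr2 = np.array([r.tr for r in records if r.session == s2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tr_r, tr_p = test_retest(tr1, tr2)
        oc_r = np.empty(k)
        oc_p = np.empty(k)
        for s in range(k):
            o1 = np.array([r.oc[s] for r in records if r.session == s1])
            o2 = np.array([r.oc[s] for r in records if r.session == s2])
            oc_r[s], oc_p[s] = test_retest(o1, o2)
    return {
        "k": k,
        "e_curve": e_curve,
        "recon_error": cb1.recon_error,
        "codebooks": (cb1, cb2),
        "state_perm": perm,
        "sequences": seqs,
        "records": records,
        "tr_r": tr_r, "tr_p": tr_p,
        "oc_r": oc_r, "oc_p": oc_p,
        "tr_session1": tr1, "tr_session2": tr2,
        "omst_fallbacks": fallbacks,
        "n_windows": n_win,
        "plan": plan,
    }


def _static_branch(store: CohortStore, band: BandSpec, estimator: str,
                   config: StudyConfig):
    fs = store.fs
    subjects, sessions = store.subjects, store.sessions
    metric_names = ("ge", "le", "strength", "passage")
    nodal: dict = {m: {ses: [] for ses in sessions} for m in metric_names}
    graphs = []
    graph_index = []
    fallbacks = 0
    for sub in subjects:
        for ses in sessions:
            x = store.get(sub, ses, band.name)
            xb = bandpass(x, band, fs)
            g = static_fcg(xb, band, estimator, fs, filter_input=False)
            raw_w = g.w.copy()
            if config.surrogates is not None:
                g, _ = statistical_filter(g, xb, fs, config.surrogates,
                                          q=config.fdr_q)
            w_f, fb = _topological(g.w, raw_w)
            fallbacks += int(fb)
            nm = nodal_metrics(w_f)
            pr = passage_probability(w_f)
            pi_nodal = (pr.pi.sum(axis=1)) / (w_f.shape[0] - 1)
            for name, vec in (("ge", nm.ge), ("le", nm.le),
                              ("strength", nm.strength), ("passage", pi_nodal)):
                nodal[name][ses].append(vec)
            graphs.append(w_f)
            graph_index.append((sub, ses))
    s1, s2 = sessions[0], sessions[-1]
    rel = {}
    for name in metric_names:
        m1 = np.vstack(nodal[name][s1])
        m2 = np.vstack(nodal[name][s2])
        r, p = nodal_reliability(m1, m2)
        rel[name] = {"r": r, "p": p,
                     "mean_r": float(np.nanmean(r))}
    dmat = gdd_matrix(graphs)
    coords, stress = mds_embed(dmat, dim=config.mds_dim)
    return {"nodal_reliability": rel, "gdd": dmat, "mds_coords": coords,
            "mds_stress": stress, "graph_index": graph_index,
            "omst_fallbacks": fallbacks}


def run_study(
    config: StudyConfig,
    store: CohortStore | None = None,
    ground_truth: GroundTruth | None = None,
) -> tuple[ReliabilityReport, dict]:
    """Execute the full static + dynamic reliability study.

    Generates the cohort from ``config.cohort`` unless a store is given.
    Returns the serializable report and a dict of rich per-band artifacts
    (codebooks, sequences, distance matrices) for further analysis.
    """
    if store is None:
        store, ground_truth = generate_cohort(config.cohort)
    artifacts: dict = {"ground_truth": ground_truth}
    results: dict = {}
    for band in store.bands:
        results[band.name] = {}
        artifacts[band.name] = {}
        for est in config.estimators:
            try:
                results[band.name][est] = _band_estimator_entry(
                    store, band, est, config, artifacts)
            except Exception as exc:  # partial failure: mark the gap
                log.exception("band %s / %s failed", band.name, est)
                results[band.name][est] = {"error": str(exc)}
    report = ReliabilityReport(results=results, seed=config.cohort.seed,
                               n_subjects=config.cohort.n_subjects)
    return report, artifacts


def _band_estimator_entry(store, band, est, config, artifacts):
    dyn = dynamic_branch(store, band, est, config,
                         seed=config.cohort.seed)
    entry = {
        "k": dyn["k"],
        "recon_error_pct": dyn["recon_error"],
        "tr_r": dyn["tr_r"], "tr_p": dyn["tr_p"],
        "oc_r": dyn["oc_r"].tolist(), "oc_p": dyn["oc_p"].tolist(),
        "n_windows": dyn["n_windows"],
        "omst_fallbacks_dynamic": dyn["omst_fallbacks"],
    }
    if config.static_branch:
        st = _static_branch(store, band, est, config)
        entry["nodal_reliability_mean_r"] = {
            m: st["nodal_reliability"][m]["mean_r"]
            for m in st["nodal_reliability"]}
        entry["mds_stress"] = st["mds_stress"]
        entry["omst_fallbacks_static"] = st["omst_fallbacks"]
        artifacts[band.name].setdefault(est, {})["static"] = st
    artifacts[band.name].setdefault(est, {})["dynamic"] = dyn
    return entry


# ---------------------------------------------------------------------------
# window optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationGrid:
    """Width/step grid in cycles; defaults span 1..10 x 0.5 and 0.1..2 x 0.1."""

    widths: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1.0, 10.01, 0.5), 3))
    steps: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.1, 2.001, 0.1), 3))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.widths), len(self.steps)

    @property
    def n_points(self) -> int:
        return len(self.widths) * len(self.steps)


def optimize_window(
    store: CohortStore,
    band: BandSpec,
    estimator: str,
    config: StudyConfig,
    grid: OptimizationGrid | None = None,
    objective=None,
    seed: int = 0,
):
    """Grid-search window width/step maximizing TR test-retest reliability.

    Re-runs the full dynamic pipeline (re-clustering included) per grid
    point unless ``objective(width, step) -> r`` is supplied.  Ties break
    toward smaller width, then smaller step.  Returns
    ``(width_cycles, step_cycles, surface)``.
    """
    if len(store.sessions) < 2:
        raise ValueError("window optimization needs a two-session cohort")
    grid = grid or OptimizationGrid()
    surface = np.full(grid.shape, np.nan)
    best = (None, None, -np.inf)
    for wi, width in enumerate(grid.widths):
        for si, step in enumerate(grid.steps):
            if step >= width:
                continue
            if objective is not None:
                r = float(objective(width, step))
            else:
                cfg = StudyConfig(
                    cohort=config.cohort,
                    window=WindowSpec(width, step,
                                      config.window.cycle_freq_rule
                                      if config.window else
                                      "band_center_arithmetic"),
                    estimators=(estimator,),
                    surrogates=config.surrogates, fdr_q=config.fdr_q,
                    k_range=config.k_range, e_threshold=config.e_threshold,
                    ng_params=config.ng_params, static_branch=False)
                dyn = dynamic_branch(store, band, estimator, cfg, seed=seed)
                r = dyn["tr_r"]
            surface[wi, si] = r
            if np.isfinite(r) and r > best[2]:
                best = (float(width), float(step), r)
    if best[0] is None:
        raise ValueError("no feasible grid point (need step < width)")
    return best[0], best[1], surface
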