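"""Statistical and topological filtering of connectivity graphs.

Statistical filtering tests each edge against a null distribution built
from single-cut surrogates: the recording is cut once at a random point
near its midpoint and the two blocks are exchanged, which preserves the
sample multiset and almost all of the phase dynamics while destroying the
cross-series alignment.  One-sided p-values (fraction of surrogate values
at or above the observed value) are corrected per graph snapshot with
Benjamini-Hochberg FDR and non-significant edges are zeroed.

Topological filtering uses orthogonal minimal spanning trees (OMST):
successive rounds extract edge-disjoint maximum-weight spanning trees
(minimal trees on 1/w distances) and the cumulative selection that
maximizes J = global efficiency - normalized cost is returned.  The result
is always connected and spans between n-1 and rounds*(n-1) edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import sparse
from scipy.sparse import csgraph
from statsmodels.stats.multitest import multipletests

from .connectivity import (
    DynamicFCGraph,
    FCGraph,
    WindowPlan,
    _corenv_matrix,
    _iplv_matrix,
)
from .metrics import components, global_efficiency, is_connected

__all__ = [
    "SurrogateScheme",
    "EdgePValues",
    "OmstResult",
    "surrogate_series",
    "edge_pvalue",
    "fdr_bh",
    "statistical_filter",
    "omst",
]


# ---------------------------------------------------------------------------
# surrogates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateScheme:
    """Single-cut surrogate parameters.

    ``n_surrogates`` defaults to 200 for desk-scale runs (1000 remains
    selectable); ``cut_halfwidth`` restricts the cut point to +-halfwidth
    seconds around the recording midpoint.
    """

    n_surrogates: int = 200
    cut_halfwidth: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 19:
            raise ValueError("need at least 19 surrogates")
        if self.cut_halfwidth <= 0:
            raise ValueError("cut_halfwidth must be positive")

    def cut_bounds(self, n_samples: int, fs: float) -> tuple[int, int]:
        half = int(round(self.cut_halfwidth * fs))
        mid = n_samples // 2
        lo, hi = mid - half, mid + half
        if lo < 1 or hi > n_samples - 1:
            raise ValueError(
                "cut window must lie strictly inside the recording "
                f"(cut_halfwidth={self.cut_halfwidth}s vs "
                f"{n_samples / fs:.1f}s recording)")
        return lo, hi


def _cut_points(scheme: SurrogateScheme, n_samples: int, fs: float,
                size: tuple) -> np.ndarray:
    lo, hi = scheme.cut_bounds(n_samples, fs)
    rng = np.random.default_rng(
        np.random.SeedSequence(scheme.seed, spawn_key=(71,)))
    return rng.integers(lo, hi + 1, size=size)


def _separated_cut_points(scheme: SurrogateScheme, n_samples: int, fs: float,
                          n_series: int) -> np.ndarray:
    """Per-draw cut points with a guaranteed pairwise separation.

    If two series of a coupled pair happen to be rotated at nearly the same
    point, their alignment -- and hence the coupling -- survives the
    surrogate transform, producing rare extreme null values that corrupt
    one-sided p-values.  Cut points are therefore drawn sequentially,
    rejecting candidates closer than ``delta`` samples to any cut already
    chosen in the draw (delta: up to 0.5 s, shrunk when many series must
    fit in the cut window).  Unlike a fixed slot grid, this keeps the
    pairwise rotation lags continuously distributed across draws, so the
    surrogate values remain ~independent samples of the null.
    """
    lo, hi = scheme.cut_bounds(n_samples, fs)
    span = hi - lo
    delta = min(int(round(0.5 * fs)), max(1, span // (3 * n_series)))
    rng = np.random.default_rng(
        np.random.SeedSequence(scheme.seed, spawn_key=(72,)))
    cuts = np.empty((scheme.n_surrogates, n_series), dtype=int)
    for s in range(scheme.n_surrogates):
        chosen: list[int] = []
        for _ in range(n_series):
            c = int(rng.integers(lo, hi + 1))
            for _attempt in range(200):
                if all(abs(c - o) >= delta for o in chosen):
                    break
                c = int(rng.integers(lo, hi + 1))
            chosen.append(c)
        cuts[s] = chosen
    return cuts


def surrogate_series(x: np.ndarray, fs: float, scheme: SurrogateScheme,
                     draw: int) -> np.ndarray:
    """Two-block rotation of ``x`` at one random cut point near the middle."""
    x = np.asarray(x)
    cut = int(_cut_points(scheme, x.shape[0], fs, (draw + 1,))[draw])
    return np.concatenate([x[cut:], x[:cut]], axis=0)


def edge_pvalue(observed: float, surrogate_values) -> float:
    """One-sided p: proportion of surrogate values >= observed (ties count)."""
    s = np.asarray(surrogate_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty surrogate distribution")
    if s.size < 19:
        raise ValueError("need at least 19 surrogate values for a p-value")
    return float(np.mean(s >= observed))


def fdr_bh(p_values, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up keep-mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    keep, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return keep.reshape(p.shape)


@dataclass
class EdgePValues:
    """Per-edge p-values for one or more graph snapshots."""

    p: np.ndarray              # (n, n) or (n_windows, n, n), symmetric
    q: float
    surrogate_values: np.ndarray = field(repr=False, default=None)  # (S, n, n)
    sided: str = "greater"


def _surrogate_tensor(
    x: np.ndarray,
    fs: float,
    estimator: str,
    scheme: SurrogateScheme,
    window: WindowPlan | None,
    env_lowpass: float | None,
) -> np.ndarray:
    """Per-draw surrogate connectivity matrices, (S, n, n).

    Each ROI is rotated at its own independent cut point so all cross-series
    alignment is destroyed while every marginal is preserved.  For dynamic
    graphs the estimator is evaluated on one window-length segment per draw
    (draw s uses window s mod n_windows), so the null has the same
    estimation length as the observed windowed values; the distribution is
    built once per recording and shared by all windows.  For static graphs
    the full length is used.
    """
    n_samp, n = x.shape
    s_count = scheme.n_surrogates
    cuts = _separated_cut_points(scheme, n_samp, fs, n)
    out = np.empty((s_count, n, n))
    idx = np.arange(n_samp)
    for s in range(s_count):
        rolled = np.empty_like(x)
        for r in range(n):
            rolled[:, r] = x[np.concatenate([idx[cuts[s, r]:], idx[:cuts[s, r]]]), r]
        a = sps.hilbert(rolled, axis=0)
        if window is None:
            seg_x, seg_a = rolled, a
        else:
            start = window.starts[s % window.n_windows]
            sl = slice(start, start + window.width)
            seg_x, seg_a = rolled[sl], a[sl]
        if estimator == "iplv":
            out[s] = _iplv_matrix(np.angle(seg_a))
        else:
            out[s] = _corenv_matrix(seg_x, seg_a, fs, env_lowpass)
    return out


def statistical_filter(
    graph: FCGraph | DynamicFCGraph,
    roi_ts: np.ndarray,
    fs: float,
    scheme: SurrogateScheme,
    q: float = 0.01,
    *,
    env_lowpass: float | None = None,
) -> tuple[FCGraph | DynamicFCGraph, EdgePValues]:
    """Zero the edges whose values are explainable by the surrogate null.

    ``roi_ts`` must be the band-limited series the graph was estimated
    from; the surrogate scheme is applied to these full-length series, not
    to individual window segments.  The test is one-sided on the signed
    value for both estimators (for CorEnv, large positive couplings are
    deemed significant; this choice is recorded here rather than inferred).
    FDR is applied independently within each snapshot's edge set.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    dynamic = isinstance(graph, DynamicFCGraph)
    window = graph.plan if dynamic else None
    if dynamic and env_lowpass is None and graph.estimator == "corenv":
        env_lowpass = 1.0 / graph.plan.width_seconds
    surr = _surrogate_tensor(roi_ts, fs, graph.estimator, scheme, window,
                             env_lowpass)
    n = roi_ts.shape[1]
    iu = np.triu_indices(n, k=1)
    surr_edges = np.sort(surr[:, iu[0], iu[1]], axis=0)  # (S, E)
    s_count = surr_edges.shape[0]

    obs = (graph.tensor if dynamic else graph.w[None])[:, iu[0], iu[1]]  # (W, E)
    p_edges = np.empty_like(obs)
    for e in range(obs.shape[1]):
        p_edges[:, e] = (s_count - np.searchsorted(
            surr_edges[:, e], obs[:, e], side="left")) / s_count

    n_snap = obs.shape[0]
    w_all = np.zeros((n_snap, n, n))
    p_all = np.zeros((n_snap, n, n))
    for wi in range(n_snap):
        keep = (fdr_bh(p_edges[wi], q) if q < 1.0
                else np.ones(obs.shape[1], dtype=bool))
        w_all[wi][iu] = np.where(keep, obs[wi], 0.0)
        w_all[wi] += w_all[wi].T
        p_all[wi][iu] = p_edges[wi]
        p_all[wi] += p_all[wi].T

    if not dynamic:
        out = FCGraph(w_all[0], estimator=graph.estimator, band=graph.band)
        return out, EdgePValues(p=p_all[0], q=q, surrogate_values=surr)
    out = DynamicFCGraph(tensor=w_all, plan=graph.plan,
                         estimator=graph.estimator, band=graph.band)
    return out, EdgePValues(p=p_all, q=q, surrogate_values=surr)


# ---------------------------------------------------------------------------
# orthogonal minimal spanning trees
# ---------------------------------------------------------------------------

@dataclass
class OmstResult:
    """Output of OMST topological filtering."""

    w_filtered: np.ndarray
    rounds_used: int
    j_curve: np.ndarray
    ge: float
    cost: float


def _max_spanning_tree_edges(w: np.ndarray) -> list[tuple[int, int]]:
    """Edges of the maximum-weight spanning tree (MST on 1/w distances)."""
    d = np.zeros_like(w)
    nz = w > 0
    d[nz] = 1.0 / w[nz]
    tree = csgraph.minimum_spanning_tree(sparse.csr_matrix(np.triu(d)))
    rows, cols = tree.nonzero()
    return [(int(i), int(j)) for i, j in zip(rows, cols)]


def omst(w: np.ndarray, max_rounds: int | None = None) -> OmstResult:
    """Orthogonal-MST topological filter maximizing J = GE - Cost.

    Round r extracts the maximum-weight spanning tree over edges not yet
    selected; after each round the cumulative selection is scored by its
    global efficiency (1/w distances) minus its normalized cost (selected
    weight / total weight).  The prefix of rounds with maximal J is
    returned.  Rounds stop when the residual graph no longer admits a
    spanning tree or after n-1 rounds.
    """
    w = np.asarray(w, dtype=float)
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("OMST expects a symmetric matrix")
    if (w < 0).any():
        raise ValueError("OMST expects nonnegative weights")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    if not is_connected(w):
        labels = components(w)
        raise ValueError(
            "OMST requires a graph connected on its nonzero support; "
            f"component labels: {labels.tolist()}")
    total = w.sum() / 2.0
    if total <= 0:
        raise ValueError("graph has no positive edges")
    if max_rounds is None:
        max_rounds = n - 1

    remaining = w.copy()
    selection = np.zeros_like(w)
    j_curve: list[float] = []
    selections: list[np.ndarray] = []
    for _ in range(max_rounds):
        if not is_connected(remaining):
            break
        edges = _max_spanning_tree_edges(remaining)
        if len(edges) < n - 1:
            break
        for i, j in edges:
            selection[i, j] = selection[j, i] = w[i, j]
            remaining[i, j] = remaining[j, i] = 0.0
        ge = global_efficiency(selection)
        cost = selection.sum() / 2.0 / total
        j_curve.append(ge - cost)
        selections.append(selection.copy())
        if remaining.sum() == 0:
            break
    best = int(np.argmax(j_curve))
    chosen = selections[best]
    ge = global_efficiency(chosen)
    cost = chosen.sum() / 2.0 / total
    return OmstResult(w_filtered=chosen, rounds_used=best + 1,
                      j_curve=np.asarray(j_curve), ge=ge, cost=cost)
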