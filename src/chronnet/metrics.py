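"""Weighted graph metrics, diffusion distance, and the common MDS space.

All shortest-path computations map edge weight w to distance 1/w, the
standard convention for weighted efficiency: strong connections are short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse
from scipy.sparse import csgraph

__all__ = [
    "NodalMetrics",
    "PassageResult",
    "DiffusionDistance",
    "nodal_metrics",
    "global_efficiency",
    "passage_probability",
    "gdd",
    "gdd_matrix",
    "mds_embed",
    "is_connected",
]


def _as_weight_matrix(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("expected a symmetric matrix")
    if (w < 0).any():
        raise ValueError("expected nonnegative weights")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


def _distance_graph(w: np.ndarray) -> sparse.csr_matrix:
    """Sparse 1/w distance graph (absent edges omitted)."""
    d = np.zeros_like(w)
    nz = w > 0
    d[nz] = 1.0 / w[nz]
    return sparse.csr_matrix(d)


def shortest_path_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths on 1/w distances."""
    return csgraph.shortest_path(_distance_graph(w), method="D", directed=False)


def is_connected(w: np.ndarray) -> bool:
    n_comp, _ = csgraph.connected_components(
        sparse.csr_matrix((np.asarray(w) != 0).astype(float)), directed=False)
    return n_comp == 1


def components(w: np.ndarray) -> np.ndarray:
    _, labels = csgraph.connected_components(
        sparse.csr_matrix((np.asarray(w) != 0).astype(float)), directed=False)
    return labels


# ---------------------------------------------------------------------------
# efficiency, strength
# ---------------------------------------------------------------------------

@dataclass
class NodalMetrics:
    """Per-node efficiency/strength summaries of one weighted graph."""

    ge: np.ndarray
    le: np.ndarray
    strength: np.ndarray
    ge_global: float
    le_global: float


def _nodal_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    if n < 2:
        return np.zeros(n)
    d = shortest_path_lengths(w)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(w: np.ndarray) -> float:
    """Mean nodal efficiency: average of 1/d_ij over ordered pairs."""
    w = _as_weight_matrix(w)
    return float(_nodal_efficiency(w).mean())


def nodal_metrics(w: np.ndarray) -> NodalMetrics:
    """Nodal global efficiency, local efficiency and strength.

    Local efficiency of node i is the efficiency of the subgraph spanned by
    i's first neighbors (i removed), normalized by k_i (k_i - 1).
    """
    w = _as_weight_matrix(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    ge = _nodal_efficiency(w)
    le = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = shortest_path_lengths(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        le[i] = inv.sum() / (k * (k - 1))
    strength = w.sum(axis=1)
    return NodalMetrics(ge=ge, le=le, strength=strength,
                        ge_global=float(ge.mean()), le_global=float(le.mean()))


# ---------------------------------------------------------------------------
# shortest-path passage probabilities (random-walk absorption)
# ---------------------------------------------------------------------------

@dataclass
class PassageResult:
    """Shortest-path arrival probabilities of a random walk.

    ``pi[i, j]`` is the probability that a walker started at i, stepping by
    the row-normalized weight matrix, is absorbed at j within exactly the
    shortest-path hop count of (i, j).  ``pi_spl`` is the off-diagonal
    mean.
    """

    pi: np.ndarray
    pi_spl: float
    spl: np.ndarray
    transition: np.ndarray


def _hop_counts(w: np.ndarray) -> np.ndarray:
    """Hop count along the minimal 1/w-distance path (ties -> fewer hops).

    Running Dijkstra on distances (1/w) with a vanishing per-hop tiebreak
    selects, among equal-length weighted paths, the one with fewest hops.
    """
    n = w.shape[0]
    d = np.zeros_like(w)
    nz = w > 0
    d[nz] = 1.0 / w[nz]
    finite = d[nz]
    eps = (finite.min() / (n + 1)) * 1e-6 if finite.size else 1.0
    d[nz] += eps
    dist, pred = csgraph.shortest_path(
        sparse.csr_matrix(d), method="D", directed=False, return_predecessors=True)
    hops = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if not np.isfinite(dist[i, j]):
                raise ValueError("graph must be connected for passage probabilities")
            h, v = 0, j
            while v != i:
                v = pred[i, v]
                h += 1
            hops[i, j] = h
    return hops


def passage_probability(w: np.ndarray) -> PassageResult:
    """Probability of reaching each target via the shortest path.

    ``pi_ij = 1 - sum_v [B_j^{L_ij}]_{iv}`` where B_j is the row-stochastic
    transition matrix with column j zeroed (j absorbing) and L_ij the hop
    count of the weighted shortest path.
    """
    w = _as_weight_matrix(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not is_connected(w):
        raise ValueError("graph must be connected for passage probabilities")
    p = w / w.sum(axis=1, keepdims=True)
    hops = _hop_counts(w)
    pi = np.zeros((n, n))
    for j in range(n):
        b = p.copy()
        b[:, j] = 0.0
        max_l = hops[:, j].max()
        power = np.eye(n)
        row_sums = {}
        for l in range(1, max_l + 1):
            power = power @ b
            row_sums[l] = power.sum(axis=1)
        for i in range(n):
            if i == j:
                continue
            pi[i, j] = 1.0 - row_sums[hops[i, j]][i]
    off = ~np.eye(n, dtype=bool)
    return PassageResult(pi=pi, pi_spl=float(pi[off].mean()), spl=hops, transition=p)


# ---------------------------------------------------------------------------
# graph diffusion distance
# ---------------------------------------------------------------------------

@dataclass
class DiffusionDistance:
    """Maximal Frobenius discrepancy between two Laplacian heat kernels."""

    d: float
    t_star: float
    eigvals: tuple[np.ndarray, np.ndarray]


def _laplacian_spectrum(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lap = np.diag(w.sum(axis=1)) - w
    vals, vecs = np.linalg.eigh(lap)
    return vals, vecs


def gdd(
    g1: np.ndarray,
    g2: np.ndarray,
    t_min: float = 1e-3,
    t_max: float = 10.0,
    n_grid: int = 60,
) -> DiffusionDistance:
    """Graph diffusion distance between two same-size graphs.

    ``d^2 = max_t || exp(-t L1) - exp(-t L2) ||_F^2`` with the matrix
    exponentials evaluated spectrally; t is searched on a log grid and
    refined by bounded scalar optimization around the best grid point.
    """
    g1 = _as_weight_matrix(g1)
    g2 = _as_weight_matrix(g2)
    if g1.shape != g2.shape:
        raise ValueError("graphs must have the same node count")
    l1_vals, l1_vecs = _laplacian_spectrum(g1)
    l2_vals, l2_vecs = _laplacian_spectrum(g2)

    def xi(t: float) -> float:
        k1 = (l1_vecs * np.exp(-t * l1_vals)) @ l1_vecs.T
        k2 = (l2_vecs * np.exp(-t * l2_vals)) @ l2_vecs.T
        diff = k1 - k2
        return float(np.sum(diff * diff))

    grid = np.logspace(np.log10(t_min), np.log10(t_max), n_grid)
    vals = np.array([xi(t) for t in grid])
    best = int(np.argmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda t: -xi(t), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    t_best, v_best = grid[best], vals[best]
    if -res.fun > v_best:
        t_best, v_best = float(res.x), float(-res.fun)
    return DiffusionDistance(d=float(np.sqrt(max(v_best, 0.0))), t_star=t_best,
                             eigvals=(l1_vals, l2_vals))


def gdd_matrix(graphs: list[np.ndarray], **kwargs) -> np.ndarray:
    """Pairwise diffusion-distance matrix over a list of graphs."""
    m = len(graphs)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = gdd(graphs[i], graphs[j], **kwargs).d
    return out


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def mds_embed(distances: np.ndarray, dim: int = 2) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) multidimensional scaling.

    Eigendecomposition of the double-centered squared-distance matrix;
    deterministic (no seed).  Returns coordinates (n x dim) and the
    stress-1 loss ``sqrt(sum (d_emb - d_in)^2 / sum d_in^2)``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any() or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distances must be nonnegative with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    emb = np.sqrt(np.maximum(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1), 0.0))
    denom = np.sum(d ** 2)
    stress = float(np.sqrt(np.sum((emb - d) ** 2) / denom)) if denom > 0 else 0.0
    return coords, stress
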