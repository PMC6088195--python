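"""Functional-connectivity microstates from dynamic graph tensors.

Each windowed graph snapshot is summarized by the ascending eigenvalue
spectrum of its Laplacian L = D - A: a permutation-invariant descriptor of
the snapshot's synchronizability structure whose dimension (n nodes) is
far below that of a vectorized graph (n(n-1)/2), sidestepping the curse of
dimensionality when clustering windows.  The pooled spectra are quantized
with the neural-gas algorithm into k prototype spectra (the microstate
codebook); assigning each window to its nearest prototype yields a
symbolic state sequence whose evolution is modeled as a first-order
Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .connectivity import DynamicFCGraph
from .metrics import is_connected

__all__ = [
    "EigenFeatures",
    "NeuralGasParams",
    "Codebook",
    "SymbolicSequence",
    "TPMatrix",
    "laplacian",
    "eigen_features",
    "neural_gas_fit",
    "reconstruction_error",
    "select_k",
    "assign_symbols",
    "match_codebooks",
    "apply_state_permutation",
    "transition_matrix",
    "prototype_topologies",
    "aggregate_networks",
]


# ---------------------------------------------------------------------------
# Laplacian eigenspectrum features
# ---------------------------------------------------------------------------

def laplacian(w: np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - A of a symmetric nonnegative matrix."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("Laplacian requires a symmetric matrix")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return np.diag(w.sum(axis=1)) - w


@dataclass
class EigenFeatures:
    """n_windows x n matrix of ascending Laplacian eigenvalues per window."""

    x: np.ndarray
    subject: int | None = None
    session: int | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))


def eigen_features(
    dfc: DynamicFCGraph | np.ndarray,
    require_connected: bool = True,
    **meta,
) -> EigenFeatures:
    """Sorted Laplacian spectrum of every window of a dynamic graph."""
    tensor = dfc.tensor if isinstance(dfc, DynamicFCGraph) else np.asarray(dfc)
    n_windows, n = tensor.shape[0], tensor.shape[1]
    x = np.empty((n_windows, n))
    for wi in range(n_windows):
        if require_connected and not is_connected(tensor[wi]):
            raise ValueError(f"window {wi}: snapshot is disconnected; "
                             "topological filtering should precede features")
        x[wi] = np.linalg.eigvalsh(laplacian(tensor[wi]))
    return EigenFeatures(x=x, **meta)


# ---------------------------------------------------------------------------
# neural-gas vector quantization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuralGasParams:
    """Neural-gas schedule: neighborhood range and step size both decay
    exponentially from start to end over all update steps."""

    n_epochs: int = 50
    lambda_start: float = 10.0
    lambda_end: float = 0.01
    eps_start: float = 0.5
    eps_end: float = 0.005


@dataclass
class Codebook:
    """k prototype vectors plus the hard assignment of training windows."""

    prototypes: np.ndarray          # (k, n)
    assignments: np.ndarray         # (n_windows,) int labels in 0..k-1
    recon_error: float              # percent
    seed: int
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.prototypes = np.atleast_2d(np.asarray(self.prototypes, dtype=float))
        self.k = self.prototypes.shape[0]

    @property
    def partition_matrix(self) -> np.ndarray:
        """Binary (n_windows x k) assignment matrix, one 1 per row."""
        u = np.zeros((self.assignments.size, self.k))
        u[np.arange(self.assignments.size), self.assignments] = 1.0
        return u


def _nearest(x: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    d2 = ((x[:, None, :] - prototypes[None, :, :]) ** 2).sum(-1)
    return np.argmin(d2, axis=1)  # ties -> lowest index


def neural_gas_fit(
    features: np.ndarray,
    k: int,
    params: NeuralGasParams = NeuralGasParams(),
    seed: int = 0,
) -> Codebook:
    """Fit a k-prototype neural-gas codebook to pooled feature rows.

    Classic rank-based soft-max adaptation: for each sample all prototypes
    move toward it with step ``eps(t) * exp(-rank / lambda(t))``, the decay
    of lambda turning the early global ordering phase into late
    winner-take-most refinement.  Deterministic under a fixed seed.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n_samples = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of windows ({n_samples})")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(41,)))
    protos = x[rng.choice(n_samples, size=k, replace=False)].copy()

    total = params.n_epochs * n_samples
    lam0, lam1 = params.lambda_start, params.lambda_end
    eps0, eps1 = params.eps_start, params.eps_end
    t = 0
    for _ in range(params.n_epochs):
        for idx in rng.permutation(n_samples):
            frac = t / max(total - 1, 1)
            lam = lam0 * (lam1 / lam0) ** frac
            eps = eps0 * (eps1 / eps0) ** frac
            diff = x[idx] - protos
            ranks = np.argsort(np.argsort((diff ** 2).sum(-1)))
            protos += (eps * np.exp(-ranks / lam))[:, None] * diff
            t += 1
    assignments = _nearest(x, protos)
    cb = Codebook(prototypes=protos, assignments=assignments,
                  recon_error=0.0, seed=seed)
    cb.recon_error = reconstruction_error(x, cb)
    return cb


def reconstruction_error(features: np.ndarray, codebook: Codebook) -> float:
    """Percent Frobenius error of replacing each row by its prototype."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("zero-norm feature matrix")
    labels = _nearest(x, codebook.prototypes)
    x_hat = codebook.prototypes[labels]
    return float(100.0 * np.linalg.norm(x - x_hat) / norm)


def select_k(
    features: np.ndarray,
    k_range=range(1, 7),
    e_threshold: float = 4.0,
    params: NeuralGasParams = NeuralGasParams(),
    seed: int = 0,
) -> tuple[int, Codebook, np.ndarray]:
    """Smallest k whose reconstruction error is below ``e_threshold`` %.

    Returns (k, codebook, error curve over k_range).  If no k satisfies the
    threshold the largest k is returned with a warning; the full curve is
    available for plateau inspection either way.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    errors = np.empty(len(ks))
    books: list[Codebook] = []
    for i, k in enumerate(ks):
        cb = neural_gas_fit(features, k, params=params, seed=seed + k)
        errors[i] = cb.recon_error
        books.append(cb)
        # error is expected to fall with k; stop early once satisfied
    for i, k in enumerate(ks):
        if errors[i] < e_threshold:
            return k, books[i], errors
    warnings.warn(f"no k in {ks} reaches reconstruction error < "
                  f"{e_threshold}%; returning largest")
    return ks[-1], books[-1], errors


@dataclass
class SymbolicSequence:
    """Per-window microstate labels for one recording."""

    labels: np.ndarray
    subject: int | None = None
    session: int | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return self.labels.size


def assign_symbols(features: np.ndarray, codebook: Codebook,
                   **meta) -> SymbolicSequence:
    """Nearest-prototype labels for each window (ties -> lowest index)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != codebook.prototypes.shape[1]:
        raise ValueError("feature dimension does not match the codebook")
    return SymbolicSequence(labels=_nearest(x, codebook.prototypes), **meta)


def match_codebooks(cb1: Codebook, cb2: Codebook) -> np.ndarray:
    """Permutation aligning cb2's states to cb1's.

    Returns ``perm`` with ``perm[i]`` = index of the cb2 prototype matched
    to cb1 prototype i, minimizing total Euclidean prototype distance over
    all permutations (exhaustive; k is small).
    """
    if cb1.k != cb2.k:
        raise ValueError("codebooks must have equal k")
    d = np.linalg.norm(cb1.prototypes[:, None, :] - cb2.prototypes[None, :, :],
                       axis=-1)
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(cb1.k)):
        cost = d[np.arange(cb1.k), perm].sum()
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return np.asarray(best_perm, dtype=int)


def apply_state_permutation(labels: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Relabel cb2-based labels into cb1's state indexing.

    ``perm`` is the output of :func:`match_codebooks`; a window labeled
    ``perm[i]`` under cb2 becomes state i.
    """
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(perm.size)
    return inverse[np.asarray(labels, dtype=int)]


@dataclass
class TPMatrix:
    """Row-stochastic k x k transition-probability matrix."""

    tp: np.ndarray
    visited: np.ndarray  # bool per state: any outgoing transition observed

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp, dtype=float)
        self.visited = np.asarray(self.visited, dtype=bool)


def transition_matrix(seq: SymbolicSequence | np.ndarray, k: int) -> TPMatrix:
    """First-order Markov transition probabilities of a state sequence.

    Counts of consecutive label pairs, row-normalized; the diagonal is the
    per-state persistence.  Rows of states never visited (as a source) are
    left at zero and flagged via ``visited``.
    """
    labels = seq.labels if isinstance(seq, SymbolicSequence) else np.asarray(seq, int)
    if labels.size < 2:
        raise ValueError("need a sequence of length >= 2")
    if labels.max() >= k or labels.min() < 0:
        raise ValueError("labels exceed the declared state count")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    row = counts.sum(axis=1)
    visited = row > 0
    tp = np.zeros_like(counts)
    tp[visited] = counts[visited] / row[visited, None]
    return TPMatrix(tp=tp, visited=visited)


def prototype_topologies(
    dfc: DynamicFCGraph | np.ndarray,
    seq: SymbolicSequence | np.ndarray,
    k: int | None = None,
) -> np.ndarray:
    """Element-wise mean graph of the windows assigned to each state."""
    tensor = dfc.tensor if isinstance(dfc, DynamicFCGraph) else np.asarray(dfc)
    labels = seq.labels if isinstance(seq, SymbolicSequence) else np.asarray(seq, int)
    if tensor.shape[0] != labels.size:
        raise ValueError("tensor windows and sequence length must match")
    if k is None:
        k = int(labels.max()) + 1
    n = tensor.shape[1]
    out = np.zeros((k, n, n))
    for s in range(k):
        mask = labels == s
        if not mask.any():
            warnings.warn(f"state {s} has no assigned windows; zero graph returned")
            continue
        out[s] = tensor[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# network-of-networks aggregation
# ---------------------------------------------------------------------------

def aggregate_networks(
    w: np.ndarray,
    partition,
    networks: tuple[str, ...] = ("DMN", "FPN", "O", "SM", "CO"),
) -> np.ndarray:
    """Collapse an ROI graph to within/between large-scale-network strength.

    ``partition`` maps each ROI index to a network name (sequence or dict).
    The diagonal holds summed within-network strength; cell (a, b) holds
    the summed strength between networks a and b (each edge counted once,
    placed symmetrically).  Use :func:`normalize_aggregates` to scale a
    collection to a common maximum of 1.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if isinstance(partition, dict):
        labels = [partition.get(i) for i in range(n)]
    else:
        labels = list(partition)
    if len(labels) != n or any(l is None for l in labels):
        raise ValueError("every ROI must be mapped to a network")
    unknown = sorted({l for l in labels if l not in networks})
    if unknown:
        raise ValueError(f"unmapped network labels: {unknown}")
    index = {name: i for i, name in enumerate(networks)}
    idx = np.array([index[l] for l in labels])
    m = len(networks)
    out = np.zeros((m, m))
    iu, ju = np.triu_indices(n, k=1)
    for i, j, val in zip(iu, ju, w[iu, ju]):
        a, b = idx[i], idx[j]
        if a == b:
            out[a, a] += val
        else:
            out[a, b] += val
            out[b, a] += val
    return out


def normalize_aggregates(mats: list[np.ndarray]) -> list[np.ndarray]:
    """Scale a collection of aggregate matrices to a shared maximum of 1."""
    peak = max(float(np.max(np.abs(m))) for m in mats)
    if peak == 0:
        return [m.copy() for m in mats]
    return [m / peak for m in mats]
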