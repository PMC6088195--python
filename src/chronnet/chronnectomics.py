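"""Chronnectomic statistics and test-retest reliability.

Chronnectomics summarize the temporal evolution of microstates: the
transition rate (fraction of consecutive windows with a state change) and
the occupancy time (fraction of windows spent in each state).  Reliability
of any per-subject statistic is the across-cohort correlation between the
two scan sessions.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .microstates import SymbolicSequence

__all__ = [
    "transition_rate",
    "occupancy",
    "test_retest",
    "nodal_reliability",
    "permutation_null",
]


def _labels(seq) -> np.ndarray:
    if isinstance(seq, SymbolicSequence):
        return seq.labels
    return np.asarray(seq, dtype=int)


def transition_rate(seq) -> float:
    """Fraction of consecutive-window state changes: transitions/(slides-1)."""
    labels = _labels(seq)
    if labels.size < 2:
        raise ValueError("need at least 2 windows for a transition rate")
    return float(np.mean(np.diff(labels) != 0))


def occupancy(seq, k: int) -> np.ndarray:
    """Fraction of windows spent in each of k states (sums to 1)."""
    labels = _labels(seq)
    if labels.size == 0:
        raise ValueError("empty sequence")
    if labels.max() >= k or labels.min() < 0:
        raise ValueError("labels exceed the declared state count")
    return np.bincount(labels, minlength=k) / labels.size


def test_retest(values_s1, values_s2, method: str = "pearson") -> tuple[float, float]:
    """Across-cohort session-1 vs session-2 correlation of a statistic.

    Pearson by default (a Spearman switch exists); subjects must be paired
    by position.  Zero variance in either vector leaves r undefined: NaN is
    returned with a warning.
    """
    v1 = np.asarray(values_s1, dtype=float)
    v2 = np.asarray(values_s2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("paired per-subject vectors of equal length required")
    if v1.size < 3:
        raise ValueError("need at least 3 subjects")
    if v1.std() == 0 or v2.std() == 0:
        warnings.warn("zero variance across subjects; reliability r undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(v1, v2)
    elif method == "spearman":
        r, p = stats.spearmanr(v1, v2)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


test_retest.__test__ = False  # a library function, not a pytest case


def nodal_reliability(metrics_s1: np.ndarray, metrics_s2: np.ndarray,
                      method: str = "pearson") -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI test-retest correlation of a nodal metric.

    Inputs are subjects x ROIs arrays (both sessions, all subjects).
    Returns (r, p) vectors of length n_rois.
    """
    m1 = np.asarray(metrics_s1, dtype=float)
    m2 = np.asarray(metrics_s2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2:
        raise ValueError("both sessions must provide subjects x ROIs arrays")
    n_rois = m1.shape[1]
    r = np.empty(n_rois)
    p = np.empty(n_rois)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_rois):
            r[i], p[i] = test_retest(m1[:, i], m2[:, i], method=method)
    return r, p


def permutation_null(values_s1, values_s2, n_perm: int = 1000,
                     seed: int = 0) -> np.ndarray:
    """Null distribution of the reliability r under subject-pairing shuffles."""
    v1 = np.asarray(values_s1, dtype=float)
    v2 = np.asarray(values_s2, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(55,)))
    out = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(v2.size)
        out[b] = np.corrcoef(v1, v2[perm])[0, 1]
    return out
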