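import warnings

import numpy as np
import pytest

import chronnet as cn
from chronnet.pipeline import StudyConfig, run_study

WIDE = cn.BandSpec("wide", 8.0, 24.0)


@pytest.fixture(scope="session")
def wide_band():
    return WIDE


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted cohort for unit-level checks (3 subjects, 160 s)."""
    cfg = cn.desk_cohort_config(n_subjects=3, seed=7, duration=160.0)
    store, gt = cn.generate_cohort(cfg)
    return cfg, store, gt


@pytest.fixture(scope="session")
def filtered_study():
    """Full two-session study on the planted desk cohort.

    Ten subjects, two sessions, 798 windows per recording, 100 surrogates
    per edge with BH-FDR q = 0.01, OMST topological filtering, per-session
    neural-gas microstates.  Shared across the recovery and reliability
    tests because it is the expensive end-to-end computation.
    """
    cfg = cn.desk_cohort_config(n_subjects=10, seed=1)
    sc = StudyConfig(
        cohort=cfg,
        window_samples=(240, 80),
        surrogates=cn.SurrogateScheme(n_surrogates=100, cut_halfwidth=10.0,
                                      seed=1),
        fdr_q=0.01,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report, artifacts = run_study(sc)
    return sc, report, artifacts


def best_permutation_accuracy(labels: np.ndarray, truth: np.ndarray,
                              k: int = 2):
    """Accuracy after the optimal state relabeling (k = 2)."""
    a1 = np.mean(labels == truth)
    a2 = np.mean((1 - labels) == truth)
    aligned = labels if a1 >= a2 else 1 - labels
    return max(a1, a2), aligned
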