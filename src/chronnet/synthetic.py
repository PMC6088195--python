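"""Synthetic two-session cohorts with planted connectivity ground truth.

Every downstream stage of the pipeline (connectivity estimation, filtering,
microstate clustering, chronnectomics, test-retest reliability) is validated
against cohorts generated here, because each recording carries a known
ground truth:

* constant phase lags between coupled regions (recoverable by iPLV),
* shared slow amplitude envelopes over (near-)orthogonal carriers
  (recoverable by orthogonalized envelope correlation),
* piecewise-stationary coupling that switches between a small set of
  planted network states according to a subject-specific first-order
  Markov chain, and
* two sessions per subject whose state dynamics agree up to a controllable
  transition-matrix jitter, so test-retest reliability is itself a planted,
  recoverable quantity.

Carriers are band-limited filtered white noise (not pure sinusoids), so
amplitude envelopes fluctuate realistically; the dedicated pair fixtures
below use deterministic constructions where an exact analytic value is
needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps

from .bands import BandSpec
from .connectivity import bandpass

__all__ = [
    "StateTemplate",
    "CohortConfig",
    "CohortStore",
    "GroundTruth",
    "two_block_templates",
    "star_templates",
    "sweep_dwell_tp",
    "decorrelated_dwell_tp",
    "desk_cohort_config",
    "generate_phase_coupled_pair",
    "generate_envelope_coupled_pair",
    "generate_cohort",
    "generate_voxel_cluster",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-seed: one global seed expands via a spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _unit_var(x: np.ndarray, axis: int = 0) -> np.ndarray:
    sd = x.std(axis=axis, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# pair fixtures
# ---------------------------------------------------------------------------

def generate_phase_coupled_pair(
    duration: float,
    fs: float,
    f_c: float,
    lag: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two narrowband series with a constant planted phase lag.

    The carrier frequency is snapped to an integer number of cycles over the
    record, so the FFT-based analytic signal is exact and a noiseless pair
    yields iPLV = \\|sin(lag)\\| to machine precision.  ``noise_sd`` adds
    independent zero-mean slow phase noise to each series.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if duration * f_c < 10:
        raise ValueError("need at least 10 carrier cycles in the record")
    n = int(round(duration * fs))
    f_eff = round(f_c * duration) / duration
    t = np.arange(n) / fs
    rng = _rng(seed, 11)
    phi0 = rng.uniform(0, 2 * np.pi)

    def phase_noise(r: np.random.Generator) -> np.ndarray:
        if noise_sd == 0:
            return np.zeros(n)
        cutoff = min(f_eff / 5.0, fs / 4.0)
        sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
        z = sps.sosfiltfilt(sos, r.standard_normal(n))
        z -= z.mean()
        sd = z.std()
        return noise_sd * z / (sd if sd > 0 else 1.0)

    x1 = np.cos(2 * np.pi * f_eff * t + phi0 + phase_noise(rng))
    x2 = np.cos(2 * np.pi * f_eff * t + phi0 - lag + phase_noise(rng))
    return x1, x2


def generate_envelope_coupled_pair(
    duration: float,
    fs: float,
    band: BandSpec,
    rho: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two band-limited series on orthogonal carriers with envelope
    correlation ``rho`` planted between their slow amplitude modulations.

    The carriers are filtered white noise, exactly orthogonalized against
    each other; each carrier's natural envelope is replaced by the planted
    slow modulator, so the Hilbert envelope of the output recovers the
    modulator and the envelope correlation is ``rho`` up to estimation
    noise.
    """
    if abs(rho) > 1:
        raise ValueError("need -1 <= rho <= 1")
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(duration * fs))
    rng = _rng(seed, 12)

    # correlated slow modulators
    f_mod = min(1.0, band.bandwidth / 4.0)
    sos = sps.butter(2, f_mod, btype="lowpass", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, rng.standard_normal((n, 2)), axis=0)
    z = (z - z.mean(0)) / z.std(0)
    z2 = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho**2)) * z[:, 1]
    a1 = np.clip(1.0 + 0.4 * z[:, 0], 0.05, None)
    a2 = np.clip(1.0 + 0.4 * z2, 0.05, None)

    # orthogonal band-limited carriers
    c = bandpass(rng.standard_normal((n, 2)), band, fs)
    c1 = c[:, 0]
    c2 = c[:, 1] - (np.dot(c1, c[:, 1]) / np.dot(c1, c1)) * c1

    def envelope_normalized(carrier: np.ndarray) -> np.ndarray:
        an = sps.hilbert(carrier)
        env = np.abs(an)
        floor = 0.1 * np.median(env)
        return np.real(an) / np.clip(env, floor, None)

    x1 = a1 * envelope_normalized(c1)
    x2 = a2 * envelope_normalized(c2)
    if noise_sd > 0:
        x1 = x1 + noise_sd * rng.standard_normal(n)
        x2 = x2 + noise_sd * rng.standard_normal(n)
    return x1, x2


def generate_voxel_cluster(
    roi_signal: np.ndarray,
    n_voxels: int,
    shared_fraction: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    standardize: bool = False,
) -> np.ndarray:
    """A block of voxel series sharing a common ROI signal.

    Each voxel is ``shared_fraction * roi_signal + noise_sd * noise``.  With
    ``standardize=True`` each row is additionally scaled to unit variance.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    roi_signal = np.asarray(roi_signal, dtype=float)
    rng = _rng(seed, 13)
    block = shared_fraction * roi_signal[None, :].repeat(n_voxels, axis=0)
    if noise_sd > 0:
        block = block + noise_sd * rng.standard_normal(block.shape)
    if standardize:
        block = _unit_var(block, axis=1)
    return block


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateTemplate:
    """A planted network state realized through a shared carrier.

    Member ROIs (finite ``offsets``) mix in a common band-limited carrier,
    phase-rotated per ROI, so the planted phase lag between members i, j is
    ``offsets[i] - offsets[j]`` and their envelopes are correlated through
    the shared carrier.  Non-member ROIs (NaN offset) stay independent of
    the state carrier.  Parameterizing states by per-ROI offsets guarantees
    the planted lag matrix is realizable (lag_ij = theta_i - theta_j).
    ``coupling`` overrides the cohort-level state coupling for this state,
    letting states differ in global synchronization strength (a spectrally
    visible signature, since the Laplacian trace scales with total weight).
    """

    offsets: np.ndarray
    name: str = "state"
    coupling: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if self.offsets.ndim != 1:
            raise ValueError("offsets must be a 1-D array (one entry per ROI)")

    @property
    def n_rois(self) -> int:
        return self.offsets.size

    @property
    def members(self) -> np.ndarray:
        return np.isfinite(self.offsets)

    @property
    def lag_matrix(self) -> np.ndarray:
        """Planted pairwise phase lags (radians); NaN outside the assembly."""
        return self.offsets[:, None] - self.offsets[None, :]

    def envelope_mask(self) -> np.ndarray:
        """Boolean matrix of pairs with planted envelope coupling."""
        m = self.members
        out = np.logical_and(m[:, None], m[None, :])
        np.fill_diagonal(out, False)
        return out


def two_block_templates(n_rois: int, spacing: float = 0.5,
                        start: float = 0.4) -> list[StateTemplate]:
    """Two states coupling disjoint halves of the ROI set.

    Offsets are spaced ``spacing`` radians apart so pairwise lags are
    bounded away from 0 and pi (where iPLV vanishes) for assemblies of up
    to ~6 members.
    """
    half = n_rois // 2
    o1 = np.full(n_rois, np.nan)
    o1[:half] = start + spacing * np.arange(half)
    o2 = np.full(n_rois, np.nan)
    o2[half:] = start + spacing * np.arange(n_rois - half)
    return [StateTemplate(o1, "state1"), StateTemplate(o2, "state2")]


def star_templates(
    n_rois: int,
    couplings: tuple[float, float] = (0.95, 0.8),
    leaf_ranges: tuple[tuple[float, float], ...] = ((1.25, 1.42), (1.18, 1.35)),
) -> list[StateTemplate]:
    """Global-synchrony states with a star-shaped phase-lag backbone.

    Every ROI participates; ROI 0 acts as hub (offset 0) and the leaves
    form two tight offset clusters near pi/2 and pi/2 + pi.  Hub-leaf lags
    are therefore strong (|sin| near 1) while every leaf-leaf lag is close
    to 0 or pi -- invisible to a zero-lag-suppressing phase estimator -- so
    the significant edge set is exactly the star, stable from window to
    window.  States differ in coupling strength, which scales the whole
    Laplacian spectrum and makes them separable by eigenspectrum
    clustering.
    """
    out = []
    for s, ((lo, hi), c) in enumerate(zip(leaf_ranges, couplings)):
        offsets = np.empty(n_rois)
        offsets[0] = 0.0
        n_leaf = n_rois - 1
        n_a = (n_leaf + 1) // 2
        base = np.linspace(lo, hi, n_leaf)
        offsets[1:1 + n_a] = base[:n_a]
        offsets[1 + n_a:] = base[n_a:] + np.pi
        out.append(StateTemplate(offsets, name=f"state{s + 1}", coupling=c))
    return out


def sweep_dwell_tp(n_subjects: int, k: int, lo: float = 0.5,
                   hi: float = 0.95) -> np.ndarray:
    """Per-subject transition matrices with dwell probability swept lo..hi.

    The sweep plants a between-subject spread in transition rate, which is
    what makes test-retest correlation of TR a meaningful planted quantity.
    """
    diags = np.linspace(lo, hi, n_subjects)
    tps = np.empty((n_subjects, k, k))
    for s, p in enumerate(diags):
        tps[s] = (1 - p) / (k - 1) if k > 1 else 0.0
        np.fill_diagonal(tps[s], p if k > 1 else 1.0)
    return tps


def decorrelated_dwell_tp(n_subjects: int, lo: float = 0.05,
                          hi: float = 0.97, shift: int = 3) -> np.ndarray:
    """Two-state transition matrices with decorrelated per-state dwell.

    State-1 dwell probabilities sweep lo..hi across subjects; state-2
    dwell follows the same sweep cyclically shifted, so subjects differ
    both in overall switching rate (driving a transition-rate spread) and
    in stationary-occupancy asymmetry (driving an occupancy spread) --
    making both chronnectomics recoverable reliability targets.
    """
    p1 = np.linspace(lo, hi, n_subjects)
    p2 = p1[(np.arange(n_subjects) + shift) % n_subjects]
    tps = np.empty((n_subjects, 2, 2))
    tps[:, 0, 0] = p1
    tps[:, 0, 1] = 1 - p1
    tps[:, 1, 1] = p2
    tps[:, 1, 0] = 1 - p2
    return tps


@dataclass
class CohortConfig:
    """Study-condition container for :func:`generate_cohort`.

    Defaults mirror a two-session resting cohort: 5-minute recordings at
    600 Hz over 90 regions.  Tests and the acceptance script use the scaled
    desk configuration from :func:`desk_cohort_config`.
    """

    n_subjects: int
    templates: list[StateTemplate]
    subject_tp: np.ndarray
    n_sessions: int = 2
    duration: float = 300.0
    fs: float = 600.0
    n_rois: int = 90
    bands: tuple[BandSpec, ...] = ()
    session_jitter: float = 0.02
    noise_sd: float = 0.05
    base_coupling: float = 0.0
    state_coupling: float = 0.65
    segment_len: float = 10.0
    stabilize_envelopes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("at least one BandSpec is required")
        self.subject_tp = np.asarray(self.subject_tp, dtype=float)
        if self.subject_tp.ndim == 2:
            self.subject_tp = np.broadcast_to(
                self.subject_tp, (self.n_subjects,) + self.subject_tp.shape
            ).copy()
        k = self.state_count
        if self.subject_tp.shape != (self.n_subjects, k, k):
            raise ValueError(
                f"subject_tp must be ({self.n_subjects}, {k}, {k}); "
                f"got {self.subject_tp.shape} (state_graphs count must match state_count)"
            )
        if not np.allclose(self.subject_tp.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("transition matrices must be row-stochastic within 1e-12")
        if (self.subject_tp < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        if self.session_jitter < 0:
            raise ValueError("session_jitter must be >= 0")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be integral")
        for tpl in self.templates:
            if tpl.n_rois != self.n_rois:
                raise ValueError("template offsets length must equal n_rois")
        if self.n_samples % self.segment_samples != 0:
            raise ValueError("segment_len must evenly divide the recording")
        c_max = max((t.coupling if t.coupling is not None else
                     self.state_coupling) for t in self.templates)
        if not (0 <= self.base_coupling + c_max < 1):
            raise ValueError("base_coupling + state coupling must lie in [0, 1)")

    @property
    def state_count(self) -> int:
        return len(self.templates)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_len * self.fs))

    @property
    def n_segments(self) -> int:
        return self.n_samples // self.segment_samples


def desk_cohort_config(
    n_subjects: int = 10,
    seed: int = 0,
    *,
    duration: float = 800.0,
    fs: float = 80.0,
    n_rois: int = 12,
    segment_len: float = 8.0,
    session_jitter: float = 0.02,
    band: BandSpec | None = None,
    dwell_lo: float = 0.05,
    dwell_hi: float = 0.97,
    templates: list[StateTemplate] | None = None,
) -> CohortConfig:
    """Scaled-down two-state study configuration used throughout the tests.

    Two global-synchrony states (strongly vs moderately phase-coupled over
    a star-shaped lag backbone) alternate under subject-specific Markov
    chains whose per-state dwell probabilities are swept (decorrelated)
    across subjects, planting between-subject spreads in both transition
    rate and occupancy.  One hundred 8-s dwell segments per recording keep
    the within-subject sampling noise of the transition count well below
    those spreads, so the planted test-retest correlations (~0.96) are
    recoverable.  The default 8-24 Hz band
    gives each analysis window an estimator bandwidth-time product
    comparable to the high-frequency bands of full-scale recordings, which
    is what makes window-level state recovery well-conditioned at this
    problem size.
    """
    band = band or BandSpec("wide", 8.0, 24.0)
    templates = templates or star_templates(n_rois)
    if len(templates) == 2:
        tp = decorrelated_dwell_tp(n_subjects, dwell_lo, dwell_hi)
    else:
        tp = sweep_dwell_tp(n_subjects, len(templates), dwell_lo, dwell_hi)
    return CohortConfig(
        n_subjects=n_subjects,
        templates=templates,
        subject_tp=tp,
        duration=duration,
        fs=fs,
        n_rois=n_rois,
        bands=(band,),
        session_jitter=session_jitter,
        segment_len=segment_len,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------

@dataclass
class CohortStore:
    """In-memory subjects x sessions x bands ROI time-series container."""

    fs: float
    bands: tuple[BandSpec, ...]
    data: dict = field(default_factory=dict)  # (sub, ses, band_name) -> (T, n)

    @property
    def subjects(self) -> list[int]:
        return sorted({k[0] for k in self.data})

    @property
    def sessions(self) -> list[int]:
        return sorted({k[1] for k in self.data})

    def get(self, subject: int, session: int, band: str) -> np.ndarray:
        return self.data[(subject, session, band)]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = self.fs
            for (sub, ses, band_name), arr in sorted(self.data.items()):
                band = next(b for b in self.bands if b.name == band_name)
                g = f.require_group(f"sub-{sub:03d}/ses-{ses}")
                d = g.create_dataset(f"band-{band_name}", data=arr,
                                     track_times=False)
                d.attrs["fs"] = self.fs
                d.attrs["f_low"] = band.f_low
                d.attrs["f_high"] = band.f_high

    @classmethod
    def from_hdf5(cls, path) -> "CohortStore":
        data = {}
        bands: dict[str, BandSpec] = {}
        with h5py.File(path, "r") as f:
            fs = float(f.attrs["fs"])
            for sub_key in f:
                sub = int(sub_key.split("-")[1])
                for ses_key in f[sub_key]:
                    ses = int(ses_key.split("-")[1])
                    for b_key, dset in f[sub_key][ses_key].items():
                        name = b_key.split("-", 1)[1]
                        bands.setdefault(
                            name,
                            BandSpec(name, float(dset.attrs["f_low"]),
                                     float(dset.attrs["f_high"])),
                        )
                        data[(sub, ses, name)] = dset[()]
        return cls(fs=fs, bands=tuple(bands.values()), data=data)


@dataclass
class GroundTruth:
    """Planted state dynamics of a generated cohort.

    ``segment_labels[(sub, ses)]`` holds the planted state per dwell
    segment; window-level labels for any analysis window plan are obtained
    from :meth:`window_labels` (state at the window's center sample).
    """

    segment_labels: dict
    segment_samples: int
    templates: list[StateTemplate]
    tp: dict
    planted_tr: dict
    planted_oc: dict

    @property
    def state_count(self) -> int:
        return len(self.templates)

    def state_at(self, subject: int, session: int, sample: int) -> int:
        labels = self.segment_labels[(subject, session)]
        return int(labels[min(sample // self.segment_samples, len(labels) - 1)])

    def window_labels(self, subject: int, session: int,
                      starts: np.ndarray, width: int) -> np.ndarray:
        labels = self.segment_labels[(subject, session)]
        centers = np.asarray(starts) + width // 2
        idx = np.minimum(centers // self.segment_samples, len(labels) - 1)
        return labels[idx]

    def to_json(self, path) -> None:
        payload = {
            "segment_samples": self.segment_samples,
            "state_count": self.state_count,
            "recordings": [
                {
                    "subject": sub,
                    "session": ses,
                    "labels": labels.tolist(),
                    "tp": self.tp[(sub, ses)].tolist(),
                    "planted_tr": self.planted_tr[(sub, ses)],
                    "planted_oc": self.planted_oc[(sub, ses)].tolist(),
                }
                for (sub, ses), labels in sorted(self.segment_labels.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _markov_labels(tp: np.ndarray, n_segments: int,
                   rng: np.random.Generator) -> np.ndarray:
    k = tp.shape[0]
    labels = np.empty(n_segments, dtype=int)
    labels[0] = rng.integers(k)
    u = rng.random(n_segments)
    cum = tp.cumsum(axis=1)
    for i in range(1, n_segments):
        labels[i] = np.searchsorted(cum[labels[i - 1]], u[i])
    return labels


def _perturb_tp(tp: np.ndarray, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    if jitter == 0:
        return tp.copy()
    noisy = np.clip(tp + jitter * rng.standard_normal(tp.shape), 1e-6, None)
    return noisy / noisy.sum(axis=1, keepdims=True)


def _rotate(analytic_carrier: np.ndarray, theta: float) -> np.ndarray:
    """Phase-rotate a band-limited carrier by ``theta`` radians."""
    return np.real(analytic_carrier * np.exp(1j * theta))


def generate_cohort(config: CohortConfig) -> tuple[CohortStore, GroundTruth]:
    """Generate a multi-subject two-session cohort with planted dynamics.

    Session 2 of each subject reuses the subject's transition matrix
    perturbed by ``session_jitter``; with jitter 0 the two sessions are
    bit-identical by construction (the sub-seed scheme keys signal content
    on the effective session, which collapses to session 1), so every
    downstream test-retest statistic is exactly 1.
    """
    cfg = config
    store = CohortStore(fs=cfg.fs, bands=cfg.bands)
    seg_labels: dict = {}
    tps: dict = {}
    planted_tr: dict = {}
    planted_oc: dict = {}
    n = cfg.n_samples
    k = cfg.state_count
    base_offsets = 0.4 + 0.45 * np.arange(cfg.n_rois)

    for sub in range(cfg.n_subjects):
        for ses in range(1, cfg.n_sessions + 1):
            ses_eff = ses if cfg.session_jitter > 0 else 1
            if ses == 1 or cfg.session_jitter == 0:
                tp = cfg.subject_tp[sub].copy()
            else:
                tp = _perturb_tp(cfg.subject_tp[sub], cfg.session_jitter,
                                 _rng(cfg.seed, sub, 1000 + ses))
            labels = _markov_labels(tp, cfg.n_segments,
                                    _rng(cfg.seed, sub, ses_eff, 0, 0))
            seg_labels[(sub, ses)] = labels
            tps[(sub, ses)] = tp
            planted_tr[(sub, ses)] = (
                float(np.mean(np.diff(labels) != 0)) if len(labels) > 1 else 0.0
            )
            planted_oc[(sub, ses)] = np.bincount(labels, minlength=k) / len(labels)

            sample_state = np.repeat(labels, cfg.segment_samples)
            for bi, band in enumerate(cfg.bands):
                x = _synthesize_recording(
                    cfg, band, labels, sample_state, base_offsets,
                    sub, ses_eff, bi,
                )
                store.data[(sub, ses, band.name)] = x

    gt = GroundTruth(
        segment_labels=seg_labels,
        segment_samples=cfg.segment_samples,
        templates=list(cfg.templates),
        tp=tps,
        planted_tr=planted_tr,
        planted_oc=planted_oc,
    )
    return store, gt


def _stabilized(c: np.ndarray) -> np.ndarray:
    """Replace a carrier's fluctuating envelope by a (near) constant one.

    Removes the Rayleigh fading of narrowband noise so planted coupling
    strength is stationary within a state; the residual phase dynamics are
    untouched.
    """
    a = sps.hilbert(c)
    env = np.abs(a)
    floor = 0.1 * np.median(env)
    out = c / np.clip(env, floor, None)
    return out / out.std()


def _synthesize_recording(
    cfg: CohortConfig,
    band: BandSpec,
    labels: np.ndarray,
    sample_state: np.ndarray,
    base_offsets: np.ndarray,
    sub: int,
    ses_eff: int,
    band_index: int,
) -> np.ndarray:
    n, m, k = cfg.n_samples, cfg.n_rois, cfg.state_count
    bkey = band_index + 1

    def carrier(purpose: int) -> np.ndarray:
        c = _unit_var(bandpass(
            _rng(cfg.seed, sub, ses_eff, bkey, purpose).standard_normal((n, 1)),
            band, cfg.fs))[:, 0]
        return _stabilized(c) if cfg.stabilize_envelopes else c

    own = _unit_var(bandpass(
        _rng(cfg.seed, sub, ses_eff, bkey, 1).standard_normal((n, m)), band, cfg.fs))
    base_a = sps.hilbert(carrier(2))

    state_rot = np.zeros((k, n, m))
    couplings = np.empty(k)
    for s, tpl in enumerate(cfg.templates):
        couplings[s] = (tpl.coupling if tpl.coupling is not None
                        else cfg.state_coupling)
        ca = sps.hilbert(carrier(3 + s))
        for i in np.flatnonzero(tpl.members):
            state_rot[s, :, i] = _rotate(ca, tpl.offsets[i])

    member = np.stack([tpl.members for tpl in cfg.templates])  # (k, m)
    c0 = cfg.base_coupling
    x = np.empty((n, m))
    w_base = np.sqrt(c0)
    for i in range(m):
        base_i = _rotate(base_a, base_offsets[i]) if c0 > 0 else 0.0
        in_state = member[sample_state, i]  # (n,) bool: ROI i coupled now?
        c_state = np.where(in_state, couplings[sample_state], 0.0)
        x[:, i] = (
            np.sqrt(1.0 - c0 - c_state) * own[:, i]
            + w_base * base_i
            + np.sqrt(c_state) * state_rot[sample_state, np.arange(n), i]
        )
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * _rng(cfg.seed, sub, ses_eff, bkey, 20).standard_normal((n, m))
    return x
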