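"""Static and sliding-window functional connectivity estimation.

Two intra-frequency estimators are provided:

* ``iplv`` -- the magnitude of the imaginary part of the phase-locking value,
  ``(1/T) |Im sum_t exp(i (phi_k(t) - phi_l(t)))|``.  Because a zero-lag
  phase difference contributes nothing to the imaginary part, iPLV is
  insensitive to instantaneous (volume-conduction-like) coupling.
* ``corenv`` -- the Pearson correlation of the slow amplitude envelopes of
  two band-limited signals after pairwise (bivariate) orthogonalization,
  which removes the linearly shared, zero-lag component before the
  envelopes are extracted.

Both estimators can be evaluated on the whole recording (static graph) or
within sliding overlapping windows (dynamic graph tensor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bands import BandSpec

__all__ = [
    "AnalyticSeries",
    "FCGraph",
    "DynamicFCGraph",
    "WindowSpec",
    "WindowPlan",
    "bandpass",
    "analytic",
    "iplv",
    "corenv",
    "window_plan",
    "static_fcg",
    "dynamic_fcg",
]

ESTIMATORS = ("iplv", "corenv")


# ---------------------------------------------------------------------------
# signal-level operations
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass filter ``x`` to ``[band.f_low, band.f_high]``.

    Uses a Butterworth filter applied forward and backward (``sosfiltfilt``),
    so the output has no phase distortion -- essential upstream of phase
    estimation.  Works along the first axis for 2-D input (samples x ROIs).
    """
    if fs <= 2.0 * band.f_high:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the band upper edge "
            f"({band.f_high} Hz)"
        )
    sos = sps.butter(order, [band.f_low, band.f_high], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


@dataclass
class AnalyticSeries:
    """Instantaneous phase and amplitude envelope of a band-limited signal."""

    phase: np.ndarray
    envelope: np.ndarray
    fs: float
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.phase.shape != self.envelope.shape:
            raise ValueError("phase/envelope shape mismatch")


def analytic(x: np.ndarray, fs: float, band: BandSpec | None = None) -> AnalyticSeries:
    """Analytic-signal (Hilbert) phase and envelope of a band-limited series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("analytic expects a 1-D series")
    if not np.any(x):
        raise ValueError("all-zero input has no defined phase")
    z = sps.hilbert(x)
    return AnalyticSeries(phase=np.angle(z), envelope=np.abs(z), fs=fs, band=band)


def _phases(a) -> np.ndarray:
    if isinstance(a, AnalyticSeries):
        return a.phase
    return np.asarray(a, dtype=float)


def iplv(a, b) -> float:
    """Imaginary phase-locking value between two phase series.

    Accepts :class:`AnalyticSeries` or raw phase arrays.  Returns
    ``(1/T) |Im sum_t exp(i dphi(t))|`` in [0, 1].
    """
    pa, pb = _phases(a), _phases(b)
    if pa.shape != pb.shape:
        raise ValueError("length mismatch between phase series")
    if pa.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.sum(np.sin(pa - pb))) / pa.size)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.linalg.norm(u) * np.linalg.norm(v)
    if denom == 0.0:
        return 0.0
    return float(np.dot(u, v) / denom)


def _smooth_envelope(env: np.ndarray, fs: float, cutoff: float | None) -> np.ndarray:
    """Low-pass the envelope at ``cutoff`` Hz (zero-phase); None = no smoothing."""
    if cutoff is None or cutoff <= 0 or cutoff >= fs / 2:
        return env
    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, env, axis=0)


def corenv(
    x: np.ndarray,
    y: np.ndarray,
    band: BandSpec | None,
    fs: float,
    *,
    filter_input: bool = True,
    env_lowpass: float | None = None,
    _rel_tol: float = 1e-10,
) -> float:
    """Orthogonalized amplitude-envelope correlation of two signals.

    Each signal is regressed on the other; the residual's envelope is
    correlated with the partner's envelope, and the two directed values are
    averaged.  A (near) zero-variance residual -- e.g. when one signal is a
    scalar multiple of the other -- contributes 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("corenv expects two equal-length 1-D series")
    if filter_input:
        if band is None:
            raise ValueError("band required when filter_input=True")
        x = bandpass(x, band, fs)
        y = bandpass(y, band, fs)
    ax, ay = sps.hilbert(x), sps.hilbert(y)

    def directed(s, a_s, t, a_t) -> float:
        # residual of t regressed on s; Hilbert transform is linear, so the
        # residual's analytic signal is a_t - beta * a_s
        ss = float(np.dot(s, s))
        if ss == 0.0:
            warnings.warn("zero-variance regressor in corenv; returning 0")
            return 0.0
        beta = float(np.dot(s, t)) / ss
        resid_a = a_t - beta * a_s
        if np.linalg.norm(resid_a) <= _rel_tol * np.linalg.norm(a_t) + 1e-300:
            warnings.warn("zero-variance residual in corenv; returning 0")
            return 0.0
        e_r = _smooth_envelope(np.abs(resid_a), fs, env_lowpass)
        e_s = _smooth_envelope(np.abs(a_s), fs, env_lowpass)
        return _pearson(e_r, e_s)

    val = 0.5 * (directed(x, ax, y, ay) + directed(y, ay, x, ax))
    return float(np.clip(val, -1.0, 1.0))


# ---------------------------------------------------------------------------
# window planning
# ---------------------------------------------------------------------------

CYCLE_FREQ_RULES = ("band_center_arithmetic", "band_low", "band_high")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry expressed in cycles of a reference frequency.

    The reference frequency is set by ``cycle_freq_rule``; the arithmetic
    band center is the default because window widths are specified as "a
    number of cycles of the studied frequency" without further qualification
    in common usage, and the center is the least arbitrary single choice.
    """

    width_cycles: float
    step_cycles: float
    cycle_freq_rule: str = "band_center_arithmetic"

    def __post_init__(self) -> None:
        if not (self.width_cycles > self.step_cycles > 0):
            raise ValueError("need width_cycles > step_cycles > 0")
        if self.cycle_freq_rule not in CYCLE_FREQ_RULES:
            raise ValueError(f"cycle_freq_rule must be one of {CYCLE_FREQ_RULES}")

    def reference_freq(self, band: BandSpec) -> float:
        if self.cycle_freq_rule == "band_low":
            return band.f_low
        if self.cycle_freq_rule == "band_high":
            return band.f_high
        return band.center


@dataclass(frozen=True)
class WindowPlan:
    """Concrete window starts/width/step in samples."""

    starts: np.ndarray
    width: int
    step: int
    fs: float

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def width_seconds(self) -> float:
        return self.width / self.fs

    @classmethod
    def from_samples(cls, n_samples: int, width: int, step: int, fs: float) -> "WindowPlan":
        if width > n_samples:
            raise ValueError(f"window width {width} exceeds n_samples {n_samples}")
        if width < 2 or step < 1:
            raise ValueError("need width >= 2 samples and step >= 1")
        count = (n_samples - width) // step + 1
        starts = np.arange(count, dtype=int) * step
        return cls(starts=starts, width=int(width), step=int(step), fs=float(fs))


def window_plan(n_samples: int, fs: float, spec: WindowSpec, band: BandSpec) -> WindowPlan:
    """Convert a cycles-based :class:`WindowSpec` to sample indices.

    ``count = floor((n_samples - width) / step) + 1`` with starts at
    ``0, step, 2*step, ...``.
    """
    f_ref = spec.reference_freq(band)
    width = int(round(spec.width_cycles / f_ref * fs))
    step = max(1, int(round(spec.step_cycles / f_ref * fs)))
    return WindowPlan.from_samples(n_samples, width, step, fs)


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------

def _check_square_symmetric(w: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(w, w.T, atol=tol):
        raise ValueError("connectivity matrix must be symmetric")
    return w


@dataclass
class FCGraph:
    """Symmetric weighted functional connectivity graph (zero diagonal)."""

    w: np.ndarray
    estimator: str
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.w = _check_square_symmetric(self.w)
        np.fill_diagonal(self.w, 0.0)
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.estimator == "iplv" and (self.w.min() < 0 or self.w.max() > 1 + 1e-9):
            raise ValueError("iPLV entries must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


@dataclass
class DynamicFCGraph:
    """Window-resolved connectivity tensor (n_windows x n x n)."""

    tensor: np.ndarray
    plan: WindowPlan
    estimator: str
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[1] != self.tensor.shape[2]:
            raise ValueError("tensor must be n_windows x n x n")
        if self.tensor.shape[0] != self.plan.n_windows:
            raise ValueError("tensor/plan window count mismatch")

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.tensor.shape[1]

    def slice(self, w: int) -> FCGraph:
        return FCGraph(self.tensor[w].copy(), estimator=self.estimator, band=self.band)


# ---------------------------------------------------------------------------
# graph estimation
# ---------------------------------------------------------------------------

def _iplv_matrix(phase: np.ndarray) -> np.ndarray:
    """All-pairs iPLV from a (T x n) phase array via one complex Gram product."""
    e = np.exp(1j * phase)
    c = e.conj().T @ e
    w = np.abs(c.imag) / phase.shape[0]
    np.fill_diagonal(w, 0.0)
    return 0.5 * (w + w.T)


def _corenv_matrix(
    x: np.ndarray,
    a: np.ndarray,
    fs: float,
    env_lowpass: float | None,
) -> np.ndarray:
    """All-pairs orthogonalized envelope correlation.

    ``x`` is the (T x n) real band-limited array, ``a`` its analytic signal.
    """
    n = x.shape[1]
    g = x.T @ x  # Gram matrix of real signals
    env = np.abs(a)
    env_s = _smooth_envelope(env, fs, env_lowpass)
    w = np.zeros((n, n))
    for k in range(n):
        for l in range(k + 1, n):
            vals = []
            for s, t in ((k, l), (l, k)):
                if g[s, s] == 0.0:
                    vals.append(0.0)
                    continue
                beta = g[s, t] / g[s, s]
                resid = a[:, t] - beta * a[:, s]
                if np.linalg.norm(resid) <= 1e-10 * np.linalg.norm(a[:, t]) + 1e-300:
                    vals.append(0.0)
                    continue
                e_r = _smooth_envelope(np.abs(resid), fs, env_lowpass)
                vals.append(_pearson(e_r, env_s[:, s]))
            w[k, l] = w[l, k] = 0.5 * (vals[0] + vals[1])
    return np.clip(w, -1.0, 1.0)


def _prepare(roi_ts: np.ndarray, band: BandSpec | None, fs: float,
             filter_input: bool) -> tuple[np.ndarray, np.ndarray]:
    roi_ts = np.asarray(roi_ts, dtype=float)
    if roi_ts.ndim != 2 or roi_ts.shape[1] < 2:
        raise ValueError("roi_ts must be samples x n with n >= 2")
    if np.isnan(roi_ts).any():
        raise ValueError("NaN in input time series")
    if filter_input:
        if band is None:
            raise ValueError("band required when filter_input=True")
        roi_ts = bandpass(roi_ts, band, fs)
    a = sps.hilbert(roi_ts, axis=0)
    return roi_ts, a


def static_fcg(
    roi_ts: np.ndarray,
    band: BandSpec | None,
    estimator: str,
    fs: float,
    *,
    filter_input: bool = True,
    env_lowpass: float | None = None,
) -> FCGraph:
    """Whole-recording connectivity graph over all ROI pairs."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    x, a = _prepare(roi_ts, band, fs, filter_input)
    if estimator == "iplv":
        w = _iplv_matrix(np.angle(a))
    else:
        w = _corenv_matrix(x, a, fs, env_lowpass)
    return FCGraph(w, estimator=estimator, band=band)


def dynamic_fcg(
    roi_ts: np.ndarray,
    band: BandSpec | None,
    estimator: str,
    fs: float,
    spec: WindowSpec | None = None,
    *,
    plan: WindowPlan | None = None,
    filter_input: bool = True,
    env_lowpass: float | str | None = "auto",
) -> DynamicFCGraph:
    """Sliding-window connectivity tensor.

    Filtering and the analytic signal are computed once on the full
    recording; each window then slices the phase (iPLV) or envelope
    (CorEnv) series.  For CorEnv, the leakage regression is estimated once
    on the full recording (leakage between two sources is a fixed geometric
    property, not a window-varying one) and ``env_lowpass="auto"`` smooths
    envelopes at 1/width Hz before windowed correlation.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    x, a = _prepare(roi_ts, band, fs, filter_input)
    if plan is None:
        if spec is None:
            raise ValueError("provide a WindowSpec or a WindowPlan")
        if band is None:
            raise ValueError("band required to convert cycles to samples")
        plan = window_plan(x.shape[0], fs, spec, band)
    n = x.shape[1]
    tensor = np.empty((plan.n_windows, n, n))
    if estimator == "iplv":
        phase = np.angle(a)
        for wi, start in enumerate(plan.starts):
            tensor[wi] = _iplv_matrix(phase[start:start + plan.width])
    else:
        cutoff = env_lowpass
        if cutoff == "auto":
            cutoff = 1.0 / plan.width_seconds
        tensor[:] = _corenv_dynamic(x, a, plan, fs, cutoff)
    return DynamicFCGraph(tensor=tensor, plan=plan, estimator=estimator, band=band)


def _corenv_dynamic(
    x: np.ndarray,
    a: np.ndarray,
    plan: WindowPlan,
    fs: float,
    env_lowpass: float | None,
) -> np.ndarray:
    n = x.shape[1]
    g = x.T @ x
    env_s = _smooth_envelope(np.abs(a), fs, env_lowpass)
    out = np.zeros((plan.n_windows, n, n))
    sl = [slice(s, s + plan.width) for s in plan.starts]
    for k in range(n):
        for l in range(k + 1, n):
            acc = np.zeros(plan.n_windows)
            n_dir = 0
            for s, t in ((k, l), (l, k)):
                if g[s, s] == 0.0:
                    n_dir += 1
                    continue
                beta = g[s, t] / g[s, s]
                resid = a[:, t] - beta * a[:, s]
                if np.linalg.norm(resid) <= 1e-10 * np.linalg.norm(a[:, t]) + 1e-300:
                    n_dir += 1
                    continue
                e_r = _smooth_envelope(np.abs(resid), fs, env_lowpass)
                e_s = env_s[:, s]
                for wi, w_sl in enumerate(sl):
                    acc[wi] += _pearson(e_r[w_sl], e_s[w_sl])
                n_dir += 1
            vals = acc / max(n_dir, 1)
            out[:, k, l] = out[:, l, k] = vals
    return np.clip(out, -1.0, 1.0)
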