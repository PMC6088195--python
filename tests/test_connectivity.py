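import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chronnet as cn
from chronnet.connectivity import WindowPlan, WindowSpec, window_plan
from chronnet.synthetic import generate_phase_coupled_pair

FS = 100.0
BAND = cn.BandSpec("alpha", 8.0, 13.0)


# ---------------------------------------------------------------------------
# bandpass / analytic
# ---------------------------------------------------------------------------

def test_bandpass_passband_preserves_tone():
    t = np.arange(0, 20, 1 / FS)
    x = np.cos(2 * np.pi * 10.0 * t)
    y = cn.bandpass(x, BAND, FS)
    core = slice(200, -200)  # away from edges
    ratio = y[core].std() / x[core].std()
    assert abs(ratio - 1.0) < 0.05


@pytest.mark.parametrize("f_out", [5.0, 26.0])  # one octave outside each edge
def test_bandpass_stopband_attenuates(f_out):
    t = np.arange(0, 20, 1 / FS)
    x = np.cos(2 * np.pi * f_out * t)
    y = cn.bandpass(x, BAND, FS)
    atten_db = 20 * np.log10(x.std() / max(y[200:-200].std(), 1e-12))
    assert atten_db >= 20.0


def test_bandpass_white_noise_power_in_band():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(60 * int(FS))
    y = cn.bandpass(x, BAND, FS)
    f, pxx = __import__("scipy.signal", fromlist=["welch"]).welch(
        y, fs=FS, nperseg=1024)
    inband = (f >= BAND.f_low) & (f <= BAND.f_high)
    assert pxx[inband].sum() / pxx.sum() >= 0.90


def test_bandpass_rejects_low_sampling_rate():
    with pytest.raises(ValueError):
        cn.bandpass(np.zeros(100), cn.BandSpec("g", 30, 60), fs=100.0)


def test_analytic_constant_envelope_and_quadrature_phase():
    t = np.arange(0, 10, 1 / FS)
    c = np.cos(2 * np.pi * 10.0 * t)
    s = np.sin(2 * np.pi * 10.0 * t)
    ac, as_ = cn.analytic(c, FS), cn.analytic(s, FS)
    core = slice(100, -100)
    env = ac.envelope[core]
    assert np.all(np.abs(env - 1.0) < 0.02)
    dphi = np.angle(np.exp(1j * (ac.phase[core] - as_.phase[core])))
    assert np.allclose(dphi, np.pi / 2, atol=1e-3)


def test_analytic_recovers_amplitude_modulator():
    t = np.arange(0, 20, 1 / FS)
    modulator = 1 + 0.5 * np.cos(2 * np.pi * 0.5 * t)
    x = modulator * np.cos(2 * np.pi * 10.0 * t)
    env = cn.analytic(x, FS).envelope
    core = slice(200, -200)
    rms = np.sqrt(np.mean((env[core] - modulator[core]) ** 2))
    assert rms / modulator[core].mean() < 0.03


def test_analytic_rejects_zero_input():
    with pytest.raises(ValueError):
        cn.analytic(np.zeros(100), FS)


# ---------------------------------------------------------------------------
# iPLV
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lag", [0.0, np.pi / 8, np.pi / 4, np.pi / 2])
def test_iplv_constant_lag_equals_abs_sin(lag):
    x1, x2 = generate_phase_coupled_pair(10, FS, 10.0, lag, 0.0, seed=3)
    v = cn.iplv(cn.analytic(x1, FS), cn.analytic(x2, FS))
    assert abs(v - abs(np.sin(lag))) < 1e-6


def test_iplv_null_distribution_small():
    rng = np.random.default_rng(5)
    hits = 0
    for _ in range(100):
        pa = rng.uniform(-np.pi, np.pi, 10_000)
        pb = rng.uniform(-np.pi, np.pi, 10_000)
        hits += cn.iplv(pa, pb) < 0.05
    assert hits >= 95


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-np.pi, np.pi),
       seed=st.integers(0, 1000))
def test_iplv_invariant_to_common_phase_and_swap(shift, seed):
    rng = np.random.default_rng(seed)
    pa = rng.uniform(-np.pi, np.pi, 500)
    pb = rng.uniform(-np.pi, np.pi, 500)
    base = cn.iplv(pa, pb)
    assert cn.iplv(pa + shift, pb + shift) == pytest.approx(base, abs=1e-10)
    assert cn.iplv(pb, pa) == pytest.approx(base, abs=1e-12)


def test_iplv_rejects_length_mismatch():
    with pytest.raises(ValueError):
        cn.iplv(np.zeros(10), np.zeros(11))


# ---------------------------------------------------------------------------
# CorEnv
# ---------------------------------------------------------------------------

def test_corenv_scaled_copy_is_zero():
    rng = np.random.default_rng(2)
    x = cn.bandpass(rng.standard_normal(60 * int(FS)), BAND, FS)
    with pytest.warns(UserWarning):
        v = cn.corenv(x, 2.5 * x, BAND, FS)
    assert v == 0.0


def test_corenv_null_independent_noise():
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(100):
        x = rng.standard_normal(30 * int(FS))
        y = rng.standard_normal(30 * int(FS))
        hits += abs(cn.corenv(x, y, BAND, FS)) < 0.15
    assert hits >= 95


def test_corenv_is_symmetric():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(20 * int(FS))
    y = rng.standard_normal(20 * int(FS))
    assert cn.corenv(x, y, BAND, FS) == pytest.approx(
        cn.corenv(y, x, BAND, FS), abs=1e-12)


# ---------------------------------------------------------------------------
# window planning
# ---------------------------------------------------------------------------

def test_window_plan_count_formula():
    plan = WindowPlan.from_samples(1000, 100, 50, FS)
    assert plan.n_windows == 19
    assert plan.starts[0] == 0 and plan.starts[1] == 50


def test_window_plan_single_window_when_width_is_full():
    plan = WindowPlan.from_samples(500, 500, 100, FS)
    assert plan.n_windows == 1


def test_window_plan_rejects_oversized_width():
    with pytest.raises(ValueError):
        WindowPlan.from_samples(100, 200, 10, FS)


def test_window_spec_delta_band_conversion():
    # width/step of {2, 0.5} cycles at the arithmetic delta-band center
    delta = cn.get_band("delta")
    spec = WindowSpec(2.0, 0.5)
    plan = window_plan(180_000, 600.0, spec, delta)
    f_ref = delta.center
    assert plan.width == round(2.0 / f_ref * 600.0)
    assert plan.step == round(0.5 / f_ref * 600.0)


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(0.5, 1.0)  # width must exceed step


# ---------------------------------------------------------------------------
# graph estimation
# ---------------------------------------------------------------------------

def test_static_fcg_planted_lag_pair():
    x1, x2 = generate_phase_coupled_pair(10, FS, 10.0, np.pi / 2, 0.0, seed=1)
    g = cn.static_fcg(np.column_stack([x1, x2]), None, "iplv", FS,
                      filter_input=False)
    assert g.w[0, 1] == pytest.approx(1.0, abs=1e-6)
    assert g.w[0, 0] == 0.0


def test_static_fcg_identical_series_zero_lag_suppressed():
    rng = np.random.default_rng(0)
    x = cn.bandpass(rng.standard_normal(2000), BAND, FS)
    g = cn.static_fcg(np.column_stack([x, x, x]), None, "iplv", FS,
                      filter_input=False)
    off = g.w[np.triu_indices(3, 1)]
    assert np.all(off < 1e-6)


def test_static_fcg_matches_pairwise_calls():
    rng = np.random.default_rng(8)
    x = cn.bandpass(rng.standard_normal((3000, 3)), BAND, FS)
    g = cn.static_fcg(x, None, "iplv", FS, filter_input=False)
    for i in range(3):
        for j in range(i + 1, 3):
            v = cn.iplv(cn.analytic(x[:, i], FS), cn.analytic(x[:, j], FS))
            assert g.w[i, j] == pytest.approx(v, abs=1e-12)


def test_static_fcg_rejects_nan():
    x = np.zeros((100, 3))
    x[0, 0] = np.nan
    with pytest.raises(ValueError):
        cn.static_fcg(x, BAND, "iplv", FS)


def test_dynamic_single_window_equals_static():
    rng = np.random.default_rng(3)
    x = cn.bandpass(rng.standard_normal((2000, 4)), BAND, FS)
    plan = WindowPlan.from_samples(2000, 2000, 100, FS)
    for est, kw in (("iplv", {}), ("corenv", {"env_lowpass": None})):
        dfc = cn.dynamic_fcg(x, None, est, FS, plan=plan, filter_input=False,
                             **kw)
        g = cn.static_fcg(x, None, est, FS, filter_input=False)
        assert np.allclose(dfc.tensor[0], g.w, atol=1e-10)


def test_dynamic_stationary_coupling_is_stable():
    # constant-lag pair with phase noise: slice-to-slice variation stays
    # small relative to the mean edge weight at width >= 8 cycles
    x1, x2 = generate_phase_coupled_pair(60, FS, 10.0, np.pi / 2, 0.3, seed=6)
    x = np.column_stack([x1, x2])
    width = int(8 / 10.0 * FS)
    plan = WindowPlan.from_samples(x.shape[0], width, width // 2, FS)
    dfc = cn.dynamic_fcg(x, None, "iplv", FS, plan=plan, filter_input=False)
    edge = dfc.tensor[:, 0, 1]
    assert edge.std() / edge.mean() < 0.3


def test_dynamic_two_regime_switch_recovered():
    rng = np.random.default_rng(11)
    n = 4000
    half = n // 2
    t = np.arange(n) / FS
    carrier = np.cos(2 * np.pi * 10 * t)
    quad = np.sin(2 * np.pi * 10 * t)
    noise = cn.bandpass(rng.standard_normal((n, 3)), BAND, FS)
    noise /= noise.std(0)
    # regime 1: ROIs 0-1 phase locked at pi/2; regime 2: ROIs 1-2 locked
    x = noise.copy() * 0.4
    x[:half, 0] += carrier[:half]
    x[:half, 1] += quad[:half]
    x[half:, 1] += carrier[half:]
    x[half:, 2] += quad[half:]
    plan = WindowPlan.from_samples(n, 400, 400, FS)
    dfc = cn.dynamic_fcg(x, None, "iplv", FS, plan=plan, filter_input=False)
    g1 = cn.static_fcg(x[:half], None, "iplv", FS, filter_input=False)
    g2 = cn.static_fcg(x[half:], None, "iplv", FS, filter_input=False)
    iu = np.triu_indices(3, 1)
    for wi in range(dfc.n_windows):
        own = g1 if plan.starts[wi] + plan.width <= half else g2
        other = g2 if own is g1 else g1
        v = dfc.tensor[wi][iu]
        c_own = np.corrcoef(v, own.w[iu])[0, 1]
        c_other = np.corrcoef(v, other.w[iu])[0, 1]
        assert c_own > 0.8 and c_own > c_other


def test_non_overlapping_windows_partition_recording():
    plan = WindowPlan.from_samples(1000, 100, 100, FS)
    ends = plan.starts + plan.width
    assert np.all(np.diff(plan.starts) == plan.width)
    assert ends[-1] <= 1000
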