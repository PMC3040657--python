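"""Waiting-time detection, Bell fitting, escape simulation, force peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unbend.constants import KBT_300K
from unbend.kinetics import (WaitingTimeRule, detect_force_peaks,
                             detect_waiting_time, fit_bell, simulate_escape)


# ---------------------------------------------------------------------------
# waiting times
# ---------------------------------------------------------------------------


def _trace(t_end=120.0, dt=0.1, base=45.0, jump_at=None, high=150.0):
    t = np.arange(0, t_end + dt, dt)
    v = np.full_like(t, base)
    if jump_at is not None:
        v[t >= jump_at] = high
    return np.column_stack([t, v])


RULE = WaitingTimeRule(baseline_window=5.0, rise_threshold=20.0, hold_time=1.0)


def test_waiting_time_ideal_step():
    assert detect_waiting_time(_trace(jump_at=50.0), RULE) == 50.0


def test_waiting_time_flat_trace_none():
    assert detect_waiting_time(_trace(), RULE) is None


def test_waiting_time_short_series_errors():
    with pytest.raises(ValueError, match="shorter"):
        detect_waiting_time(_trace(t_end=4.0), RULE)


def _brute_force_waiting(series, rule):
    t, v = series[:, 0], series[:, 1]
    baseline = v[t <= t[0] + rule.baseline_window].mean()
    level = baseline + rule.rise_threshold
    for i in range(len(t)):
        if v[i] <= level:
            continue
        j = i
        while j < len(t) and v[j] > level:
            j += 1
        if t[j - 1] - t[i] >= rule.hold_time:
            return float(t[i])
    return None


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_waiting_time_matches_scan_oracle(seed):
    """Noisy two-state traces: detector equals the exhaustive scan."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, 80.0, 0.2)
    jump = rng.uniform(10, 60)
    v = 45 + 3 * rng.normal(size=len(t)) + np.where(t >= jump, 100.0, 0.0)
    series = np.column_stack([t, v])
    assert detect_waiting_time(series, RULE) == _brute_force_waiting(series, RULE)


def test_waiting_time_ignores_content_after_detection():
    base = _trace(jump_at=50.0)
    wt = detect_waiting_time(base, RULE)
    modified = base.copy()
    modified[-100:, 1] = 0.0   # drop back long after the hold window
    assert detect_waiting_time(modified, RULE) == wt


# ---------------------------------------------------------------------------
# Bell fit
# ---------------------------------------------------------------------------


def test_fit_bell_exact_loglinear_input():
    """t0 = 100 ns, Δx = 2 Å at forces {0, kBT/2, kBT} per Å."""
    t0, dx = 100.0, 2.0
    forces = np.array([0.0, 20.70975, 41.4195])
    times = t0 * np.exp(-forces * dx / KBT_300K)
    np.testing.assert_allclose(times, [100.0, 36.78794, 13.53353], rtol=1e-5)
    fit = fit_bell(list(zip(forces, times)))
    assert fit.t0 == pytest.approx(t0, abs=1e-6)
    assert fit.dx == pytest.approx(dx, abs=1e-6)
    assert fit.r2 == pytest.approx(1.0)


def test_fit_bell_two_points_exact():
    fit = fit_bell([(50.0, 30.0), (150.0, 3.0)])
    assert np.allclose(fit.residuals, 0.0)
    assert fit.t0_se == 0.0 and fit.dx_se == 0.0


def test_fit_bell_input_validation():
    with pytest.raises(ValueError):
        fit_bell([(50.0, 30.0)])
    with pytest.raises(ValueError, match="positive"):
        fit_bell([(50.0, -1.0), (100.0, 3.0)])
    with pytest.raises(ValueError, match="distinct"):
        fit_bell([(50.0, 3.0), (50.0, 4.0)])


@settings(max_examples=30, deadline=None)
@given(t0=st.floats(1.0, 1e4), dx=st.floats(0.1, 5.0))
def test_fit_bell_identity_on_exact_data(t0, dx):
    forces = np.linspace(20, 200, 6)
    times = t0 * np.exp(-forces * dx / KBT_300K)
    fit = fit_bell(list(zip(forces, times)))
    assert fit.t0 == pytest.approx(t0, rel=1e-8)
    assert fit.dx == pytest.approx(dx, rel=1e-8)


def test_fit_bell_recovers_from_simulated_ensembles():
    """Fitting ln(mean) per force over many replicates centers on truth."""
    t0, dx = 728.0, 1.2
    forces = [97.0, 122.0, 146.0, 170.0, 195.0]
    dxs = []
    for rep in range(200):
        draws = simulate_escape(t0, dx, forces, samples_per_force=100,
                                seed=rep)
        means = [(f, draws[draws[:, 0] == f, 1].mean()) for f in forces]
        dxs.append(fit_bell(means).dx)
    sem = np.std(dxs) / np.sqrt(len(dxs))
    assert abs(np.mean(dxs) - dx) < 2 * sem + 1e-3


def test_single_sample_log_fit_underestimates_t0():
    """E[ln t] = ln τ − γ_Euler: one-sample ln-fits deflate t0 by e^(−γ);
    fitting ln(mean waiting time) removes the bias."""
    t0, dx = 728.0, 1.2
    forces = [97.0, 122.0, 146.0, 170.0, 195.0]
    single_t0, mean_t0 = [], []
    for rep in range(400):
        draws = simulate_escape(t0, dx, forces, samples_per_force=200,
                                seed=10_000 + rep)
        singles = [(f, draws[draws[:, 0] == f, 1][0]) for f in forces]
        means = [(f, draws[draws[:, 0] == f, 1].mean()) for f in forces]
        single_t0.append(fit_bell(singles).t0)
        mean_t0.append(fit_bell(means).t0)
    single_t0 = np.array(single_t0)
    mean_t0 = np.array(mean_t0)
    euler_gamma = 0.5772156649
    log_single = np.log(single_t0)
    log_mean = np.log(mean_t0)
    sem_s = log_single.std() / np.sqrt(len(log_single))
    sem_m = log_mean.std() / np.sqrt(len(log_mean))
    # E[intercept] with one ln t sample per force is ln t0 − γ_Euler
    assert abs(log_single.mean() - (np.log(t0) - euler_gamma)) < 3 * sem_s
    # fitting ln(mean waiting time) is unbiased
    assert abs(log_mean.mean() - np.log(t0)) < 3 * sem_m + 0.01
    assert log_single.mean() < log_mean.mean() - 5 * sem_m


# ---------------------------------------------------------------------------
# escape simulation
# ---------------------------------------------------------------------------


def test_escape_force_independent_when_dx_zero():
    draws = simulate_escape(100.0, 0.0, [0.0, 100.0, 200.0],
                            samples_per_force=10_000, seed=1)
    for f in (0.0, 100.0, 200.0):
        assert draws[draws[:, 0] == f, 1].mean() == pytest.approx(100.0,
                                                                  rel=0.05)


def test_escape_zero_force_mean_is_t0():
    draws = simulate_escape(728.0, 1.2, [0.0], samples_per_force=10_000,
                            seed=2)
    assert draws[:, 1].mean() == pytest.approx(728.0, rel=0.05)


def test_escape_mean_matches_closed_form_tau():
    """At 195 pN with the fitted parameters, τ = t0·e^(−FΔx/kBT) ≈ 2.57 ns."""
    tau = 728.0 * np.exp(-195.0 * 1.2 / KBT_300K)
    assert tau == pytest.approx(2.566, abs=0.01)
    draws = simulate_escape(728.0, 1.2, [195.0], samples_per_force=10_000,
                            seed=3)
    assert draws[:, 1].mean() == pytest.approx(tau, rel=0.05)


def test_escape_convergence_rate():
    """Relative error of the sample mean shrinks like 1/sqrt(n)."""
    for n in (100, 10_000):
        draws = simulate_escape(50.0, 0.0, [0.0], samples_per_force=n, seed=4)
        rel_err = abs(draws[:, 1].mean() - 50.0) / 50.0
        assert rel_err < 3.0 / np.sqrt(n)


def test_escape_reproducible_and_validated():
    a = simulate_escape(10.0, 1.0, [50.0], samples_per_force=5, seed=9)
    b = simulate_escape(10.0, 1.0, [50.0], samples_per_force=5, seed=9)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        simulate_escape(-1.0, 1.0, [50.0], seed=0)


# ---------------------------------------------------------------------------
# force peaks
# ---------------------------------------------------------------------------


def test_single_triangular_peak():
    ext = np.linspace(0, 40, 81)
    force = 300.0 - 15.0 * np.abs(ext - 20.0)
    peaks = detect_force_peaks(np.column_stack([ext, force]),
                               smoothing_window=0.0)
    assert len(peaks) == 1
    assert peaks[0].extension == pytest.approx(20.0)
    assert peaks[0].force == pytest.approx(300.0)


def test_two_pulses_ranked_by_prominence():
    ext = np.linspace(0, 100, 401)
    force = (200 * np.exp(-0.5 * ((ext - 25) / 4) ** 2)
             + 120 * np.exp(-0.5 * ((ext - 70) / 4) ** 2))
    peaks = detect_force_peaks(np.column_stack([ext, force]),
                               smoothing_window=0.0)
    assert len(peaks) == 2
    assert peaks[0].extension == pytest.approx(25.0, abs=0.5)
    assert peaks[1].extension == pytest.approx(70.0, abs=0.5)
    assert peaks[0].prominence > peaks[1].prominence


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_peaks_match_scipy_prominences(seed):
    """Local maxima + prominences agree with scipy.signal on random curves."""
    from scipy.signal import find_peaks, peak_prominences
    rng = np.random.default_rng(seed)
    ext = np.arange(0, 60.0, 0.5)
    force = np.abs(np.cumsum(rng.normal(size=len(ext)))) * 10
    curve = np.column_stack([ext, force])
    ours = detect_force_peaks(curve, smoothing_window=0.0, min_prominence=5.0)
    idx, _ = find_peaks(force)
    prom = peak_prominences(force, idx)[0]
    keep = prom >= 5.0
    expected = sorted(zip(prom[keep], ext[idx[keep]]), key=lambda p: -p[0])
    assert len(ours) == len(expected)
    for got, (p, e) in zip(ours, expected):
        assert got.extension == pytest.approx(e)
        assert got.prominence == pytest.approx(p)


def test_peak_window_validation():
    curve = np.column_stack([np.linspace(0, 2, 10), np.ones(10)])
    with pytest.raises(ValueError, match="window"):
        detect_force_peaks(curve, smoothing_window=10.0)
    with pytest.raises(ValueError, match="sorted"):
        detect_force_peaks(curve[::-1], smoothing_window=0.0)
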