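"""Waiting times, Bell-model kinetics, escape simulation, force peaks.

The unbending of a bent molecule under constant force is modelled as
thermally activated escape over a single barrier.  The Bell model gives
the mean waiting time

    t(F) = t0 · exp(−F·Δx / kB·T)

where t0 is the zero-force waiting time and Δx the width of the energy
well trapping the bent state.  Fitting is done by ordinary least squares
of ln t on F, so Δx = −slope·kB·T and t0 = exp(intercept); standard
errors come from the regression covariance (delta method for t0).

When several waiting-time samples per force are available the fit should
use ln(mean waiting time): fitting single-sample ln t per force is biased
because E[ln t] = ln τ − γ_Euler for an exponential variable, which
deflates t0 by the factor e^(−γ) ≈ 0.561 while leaving Δx unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kbt

__all__ = ["WaitingTimeRule", "BellFitResult", "ForcePeak",
           "detect_waiting_time", "fit_bell", "simulate_escape",
           "detect_force_peaks"]


@dataclass(frozen=True)
class WaitingTimeRule:
    """Onset rule: baseline mean + δ sustained for the hold time."""

    baseline_window: float = 5.0   # ns averaged to define the baseline
    rise_threshold: float = 20.0   # Å above baseline that marks unbending
    hold_time: float = 1.0         # ns the rise must persist

    def __post_init__(self) -> None:
        if min(self.baseline_window, self.rise_threshold, self.hold_time) <= 0:
            raise ValueError("all waiting-time rule fields must be positive")


@dataclass
class BellFitResult:
    """Bell-model fit: t0 (ns), Δx (Å), standard errors, diagnostics."""

    t0: float
    dx: float
    t0_se: float
    dx_se: float
    kbt: float                 # pN·Å used in the conversion
    r2: float
    n_points: int
    residuals: np.ndarray      # in ln t

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")


@dataclass(frozen=True)
class ForcePeak:
    """A local maximum of the force-extension curve."""

    extension: float    # Å
    force: float        # pN
    prominence: float   # pN

    def __post_init__(self) -> None:
        if self.prominence < 0:
            raise ValueError("prominence must be >= 0")


def detect_waiting_time(series: np.ndarray, rule: WaitingTimeRule = WaitingTimeRule()):
    """Unbending onset time from a head-tail distance trace.

    The baseline is the mean over the initial ``baseline_window``; the
    waiting time is the first time the trace exceeds baseline + δ and
    stays above for at least the hold time.  Returns ``None`` if the
    trace never sustains the rise.
    """
    s = np.asarray(series, dtype=float)
    t, v = s[:, 0], s[:, 1]
    span = t[-1] - t[0]
    if span < rule.baseline_window + rule.hold_time:
        raise ValueError("series shorter than baseline window + hold time")
    base_mask = t <= t[0] + rule.baseline_window
    baseline = float(v[base_mask].mean())
    level = baseline + rule.rise_threshold
    above = v > level
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if t[j - 1] - t[i] >= rule.hold_time:
            return float(t[i])
        i = j
    return None


def fit_bell(points, temperature_k: float = 300.0) -> BellFitResult:
    """Fit t = t0·exp(−F·Δx/kB·T) by OLS of ln t on F.

    ``points`` is a sequence of (force_pN, waiting_time_ns) pairs with
    distinct forces and positive times.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least 2 (force, time) points")
    f, wt = pts[:, 0], pts[:, 1]
    if np.any(wt <= 0):
        raise ValueError("waiting times must be positive")
    if len(np.unique(f)) < 2:
        raise ValueError("need at least 2 distinct forces")
    kt = kbt(temperature_k)
    lnt = np.log(wt)
    n = len(f)
    fbar = f.mean()
    sxx = float(np.sum((f - fbar) ** 2))
    slope = float(np.sum((f - fbar) * (lnt - lnt.mean())) / sxx)
    intercept = float(lnt.mean() - slope * fbar)
    resid = lnt - (intercept + slope * f)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((lnt - lnt.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if n > 2:
        sigma2 = ss_res / (n - 2)
        slope_se = np.sqrt(sigma2 / sxx)
        intercept_se = np.sqrt(sigma2 * (1.0 / n + fbar ** 2 / sxx))
    else:
        slope_se = intercept_se = 0.0
    t0 = float(np.exp(intercept))
    return BellFitResult(
        t0=t0,
        dx=-slope * kt,
        t0_se=t0 * float(intercept_se),     # delta method
        dx_se=float(slope_se) * kt,
        kbt=kt,
        r2=min(max(r2, 0.0), 1.0),
        n_points=n,
        residuals=resid,
    )


def simulate_escape(t0: float, dx: float, forces, temperature_k: float = 300.0,
                    samples_per_force: int = 1, seed: int = 0) -> np.ndarray:
    """Draw exponential waiting times with mean t0·exp(−F·Δx/kB·T).

    Returns an array of (force_pN, waiting_time_ns) rows, seeded and
    reproducible; the two-state escape stand-in for constant-force runs.
    """
    if t0 <= 0 or samples_per_force < 1:
        raise ValueError("t0 and samples_per_force must be positive")
    kt = kbt(temperature_k)
    rng = np.random.default_rng(seed)
    rows = []
    for f in np.asarray(forces, dtype=float):
        tau = t0 * np.exp(-f * dx / kt)
        rows.append(np.column_stack([
            np.full(samples_per_force, f),
            rng.exponential(tau, size=samples_per_force),
        ]))
    return np.concatenate(rows, axis=0)


def _smooth(ext: np.ndarray, force: np.ndarray, window: float) -> np.ndarray:
    """Centered moving average of force over an extension window."""
    out = np.empty_like(force)
    half = window / 2.0
    for i, x in enumerate(ext):
        m = (ext >= x - half) & (ext <= x + half)
        out[i] = force[m].mean()
    return out


def _prominence(force: np.ndarray, peak: int) -> float:
    """Topographic prominence of a local maximum on a 1-D curve."""
    h = force[peak]
    higher_left = np.flatnonzero(force[:peak] > h)
    higher_right = peak + 1 + np.flatnonzero(force[peak + 1:] > h)
    lo = int(higher_left[-1]) if len(higher_left) else 0
    hi = int(higher_right[0]) if len(higher_right) else len(force) - 1
    left_base = force[lo:peak + 1].min()
    right_base = force[peak:hi + 1].min()
    return float(h - max(left_base, right_base))


def detect_force_peaks(curve: np.ndarray, smoothing_window: float = 2.0,
                       min_prominence: float = 0.0) -> list:
    """Local maxima of a smoothed force-extension curve, by prominence.

    ``curve`` is an array of (extension_A, force_pN) sorted by extension.
    Returns :class:`ForcePeak` objects in decreasing prominence order;
    the first is the major peak.
    """
    c = np.asarray(curve, dtype=float)
    ext, force = c[:, 0], c[:, 1]
    if np.any(np.diff(ext) < 0):
        raise ValueError("curve must be sorted by extension")
    if smoothing_window > ext[-1] - ext[0]:
        raise ValueError("smoothing window larger than the curve span")
    sm = _smooth(ext, force, smoothing_window) if smoothing_window > 0 else force
    peaks = []
    for i in range(1, len(sm) - 1):
        if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]:
            prom = _prominence(sm, i)
            if prom >= min_prominence and prom > 0:
                peaks.append(ForcePeak(extension=float(ext[i]),
                                       force=float(sm[i]),
                                       prominence=prom))
    peaks.sort(key=lambda p: (-p.prominence, p.extension))
    return peaks
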