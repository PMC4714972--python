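"""Oscillation classification and period estimation.

Two estimators are provided.  The autocorrelation estimator computes

    R(tau) = integral over [T1, T2] of p(t + tau) p(t) dt

on the mean-subtracted post-transient signal and takes the period as the
smallest positive lag at which R attains a local maximum (mean subtraction
removes the constant offset a nonzero mean adds to R; it does not move the
peak locations for a sustained oscillation, and makes shallow peaks
detectable).  The peak-to-peak estimator averages successive intervals
between prominence-filtered signal peaks, the procedure used for
experimental fluorescence traces.

A trace is classified oscillatory when (i) a qualifying periodicity signal
exists (autocorrelation peak, or >= 3 detected peaks), (ii) the settled
peak-to-trough amplitude -- measured on the second half of the
post-transient window -- exceeds 1% of the signal mean, and (iii) the
oscillation is sustained: the second-half amplitude is at least 75% of the
first-half amplitude.  The sustainedness test rejects slowly decaying
transients near a Hopf boundary, which otherwise masquerade as
oscillations over any finite horizon; a limit cycle holds the ratio at 1.
The amplitude and sustainedness cutoffs are this package's own
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .network import ReactorSettings, RingNetwork, RingState
from .simulate import Trajectory, simulate

__all__ = [
    "PeriodEstimate",
    "SweepResult",
    "autocorrelation_period",
    "peak_to_peak_period",
    "period_vs_dilution",
    "oscillation_range_vs_template",
]

#: autocorrelation peak must rise by this fraction of R(0) to count
ACF_PROMINENCE = 0.05
#: relative peak-to-trough amplitude below which a trace is "stable"
AMPLITUDE_CUTOFF = 0.01
#: second-half amplitude must be at least this fraction of the first-half's
SUSTAIN_RATIO = 0.75
#: prominence for experimental-style peak detection, fraction of signal range
PEAK_PROMINENCE = 0.10
#: fraction of the trace discarded as transient by default
TRANSIENT_FRACTION = 0.40


@dataclass
class PeriodEstimate:
    oscillatory: bool
    period: float | None = None          # minutes
    amplitude: float = 0.0               # nM, peak-to-trough post-transient
    method: str = "autocorrelation"
    T1: float = 0.0
    T2: float = 0.0
    intervals: np.ndarray | None = None  # per-interval periods (peak_to_peak)
    note: str = ""


@dataclass
class SweepResult:
    t_d: np.ndarray
    estimates: list[PeriodEstimate]
    oscillatory_range: tuple[float, float] | None

    def periods(self) -> np.ndarray:
        """Periods in minutes, NaN where not oscillatory."""
        return np.array([e.period if e.oscillatory else np.nan for e in self.estimates])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t_d_min": self.t_d,
            "oscillatory": [e.oscillatory for e in self.estimates],
            "period_min": self.periods(),
            "amplitude_nM": [e.amplitude for e in self.estimates],
        })


def _window(times: np.ndarray, signal: np.ndarray, T1: float | None, T2: float | None):
    times = np.asarray(times, float)
    signal = np.asarray(signal, float)
    if times.size != signal.size:
        raise ValueError("times and signal must have equal length")
    span = times[-1] - times[0]
    if T1 is None:
        T1 = times[0] + TRANSIENT_FRACTION * span
    if T2 is None:
        T2 = times[-1]
    if not T1 < T2:
        raise ValueError(f"need T1 < T2, got T1={T1}, T2={T2}")
    mask = (times >= T1) & (times <= T2)
    t, x = times[mask], signal[mask]
    if t.size < 8:
        raise ValueError("analysis window contains too few samples")
    note = ""
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * np.max(dt):   # non-uniform: resample
        tu = np.linspace(t[0], t[-1], t.size)
        x = np.interp(tu, t, x)
        t = tu
        note = "resampled to uniform grid"
    return t, x, float(T1), float(T2), note


def _amplitude(x: np.ndarray) -> float:
    return float(np.max(x) - np.min(x))


def _sustained(x: np.ndarray) -> bool:
    """Settled amplitude above cutoff and not decaying across the window."""
    half = x.size // 2
    a1, a2 = _amplitude(x[:half]), _amplitude(x[half:])
    mean = float(np.mean(np.abs(x)))
    if mean == 0.0:
        return False
    if a2 <= AMPLITUDE_CUTOFF * mean:
        return False
    return a1 == 0.0 or a2 >= SUSTAIN_RATIO * a1


def autocorrelation_period(times: np.ndarray, signal: np.ndarray,
                           T1: float | None = None, T2: float | None = None) -> PeriodEstimate:
    """Period from the first qualifying local maximum of the autocorrelation.

    The lag of the first local maximum of R with prominence at least 5% of
    R(0) is refined by parabolic interpolation through the three samples
    around the peak.
    """
    t, x, T1, T2, note = _window(times, signal, T1, T2)
    amp = _amplitude(x)
    if not _sustained(x):
        return PeriodEstimate(False, None, amp, "autocorrelation", T1, T2, note=note)
    dt = t[1] - t[0]
    xc = x - np.mean(x)
    N = xc.size
    # unbiased normalization: the raw windowed correlation carries a
    # triangular overlap taper that drags peak positions toward zero lag
    R = np.correlate(xc, xc, mode="full")[N - 1:] / (N - np.arange(N))
    R = R[: max(3 * N // 4, 3)]   # keep lags with substantial overlap
    if R[0] <= 0:
        return PeriodEstimate(False, None, amp, "autocorrelation", T1, T2, note=note)
    peaks, _ = find_peaks(R, prominence=ACF_PROMINENCE * R[0])
    peaks = peaks[peaks > 0]
    if peaks.size == 0:
        return PeriodEstimate(False, None, amp, "autocorrelation", T1, T2, note=note)
    k = int(peaks[0])   # smallest positive lag
    if 0 < k < R.size - 1:
        denom = R[k - 1] - 2.0 * R[k] + R[k + 1]
        shift = 0.5 * (R[k - 1] - R[k + 1]) / denom if denom != 0 else 0.0
        lag = (k + np.clip(shift, -0.5, 0.5)) * dt
    else:
        lag = k * dt
    return PeriodEstimate(True, float(lag), amp, "autocorrelation", T1, T2, note=note)


def peak_to_peak_period(times: np.ndarray, signal: np.ndarray,
                        T1: float | None = None, T2: float | None = None) -> PeriodEstimate:
    """Mean interval between successive signal peaks (experimental-trace style).

    Peaks are detected with prominence at least 10% of the post-transient
    signal range; fewer than 3 peaks means the trace is not classified as
    oscillatory.  Per-interval values are kept for dispersion analysis.
    """
    t, x, T1, T2, note = _window(times, signal, T1, T2)
    amp = _amplitude(x)
    if not _sustained(x):
        return PeriodEstimate(False, None, amp, "peak_to_peak", T1, T2, note=note)
    # light smoothing so measurement noise does not spawn spurious peaks
    xs = x
    if x.size >= 25:
        from scipy.signal import savgol_filter
        window = min(31, max(5, (x.size // 20) | 1))
        xs = savgol_filter(x, window, polyorder=2)
    peaks, _ = find_peaks(xs, prominence=PEAK_PROMINENCE * _amplitude(xs))
    if peaks.size < 3:
        return PeriodEstimate(False, None, amp, "peak_to_peak", T1, T2, note=note)
    intervals = np.diff(t[peaks])
    return PeriodEstimate(True, float(np.mean(intervals)), amp, "peak_to_peak",
                          T1, T2, intervals=intervals, note=note)


def classify_trajectory(traj: Trajectory, species: str = "p1",
                        method: str = "autocorrelation") -> PeriodEstimate:
    """Run a period estimator on one species of a simulated trajectory."""
    est = (autocorrelation_period if method == "autocorrelation"
           else peak_to_peak_period)
    return est(traj.times, traj.species(species))


def period_vs_dilution(net: RingNetwork, t_d_grid, mode: str = "continuous",
                       horizon: float | None = None,
                       init: RingState | None = None) -> SweepResult:
    """Simulate and classify the network across a grid of dilution times."""
    t_d_grid = np.asarray(t_d_grid, float)
    if t_d_grid.ndim != 1 or not np.all(np.diff(t_d_grid) > 0):
        raise ValueError("t_d grid must be 1-D and strictly increasing")
    if init is None:
        init = RingState.pulse(net.n)
    estimates = []
    for t_d in t_d_grid:
        reactor = ReactorSettings.from_dilution_time(float(t_d), mode=mode)
        traj = simulate(net, reactor, init, horizon=horizon)
        estimates.append(classify_trajectory(traj))
    osc = t_d_grid[[e.oscillatory for e in estimates]]
    rng = (float(osc.min()), float(osc.max())) if osc.size else None
    return SweepResult(t_d=t_d_grid, estimates=estimates, oscillatory_range=rng)


def oscillation_range_vs_template(net: RingNetwork, g_grid, t_d_grid,
                                  horizon: float | None = None) -> dict[float, tuple | None]:
    """Oscillatory dilution-time range at each template (plasmid) concentration."""
    g_grid = np.asarray(g_grid, float)
    if np.any(g_grid < 0):
        raise ValueError("template concentrations must be nonnegative")
    out: dict[float, tuple | None] = {}
    for g in g_grid:
        if g == 0.0:
            out[float(g)] = None   # no synthesis, no oscillation at any t_d
            continue
        sweep = period_vs_dilution(net.replace(g=float(g)), t_d_grid, horizon=horizon)
        out[float(g)] = sweep.oscillatory_range
    return out
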