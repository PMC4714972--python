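"""Repressor-promoter transfer-function inference.

The reactor measures only mature (fluorescent) reporter protein, diluted in
discrete steps.  Between steps, synthesis feeds a dark pool P_d that matures
into the fluorescent pool P_f at rate ``mat``; each step removes a volume
fraction ``dil`` of both pools.  The forward recursion over one step
interval dt is

    P_d(t+dt) = P_d(t) + syn(t) dt - mat P_d(t) dt - dil P_d(t)
    P_f(t+dt) = P_f(t) + mat P_d(t) dt - dil P_f(t)

which inverts exactly: the dark pool follows from the fluorescence
increments,

    P_d(t) = (P_f(t+dt) - P_f(t) + dil P_f(t)) / (mat dt)

and the synthesis rate from the dark-pool increments,

    syn(t) = (P_d(t+dt) - P_d(t) + mat P_d(t) dt + dil P_d(t)) / dt.

A transfer curve plots the normalized synthesis rate of the reporter driven
by the promoter of interest against the total (dark + fluorescent)
repressor-reporter concentration, taken on the descending branch of a
repressor-template ramp and restricted to repressor concentrations above
1 nM.  The curve is fit to a Hill repression law

    y = ymin + (1 - ymin) K_M^n / (K_M^n + x^n)

by orthogonal-distance (errors-in-variables) regression with 9% relative
errors on both coordinates, since repressor concentration and synthesis
rate are both inferred from noisy fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "TransferCurve",
    "HillTransferModel",
    "HillFitResults",
    "infer_dark_protein",
    "infer_synthesis_rate",
    "assemble_transfer_curve",
    "fit_hill",
    "normalize_vmax",
    "hill_repression",
    "maturation_rate_from_time",
]

#: the assumed relative measurement error on both coordinates
MEASUREMENT_ERROR = 0.09
#: repressor concentrations at or below this are discarded (nM)
MIN_REPRESSOR = 1.0

# measured maturation times: 15 min (Cerulean), 29 min (Citrine)
MATURATION_TIME_CERULEAN = 15.0
MATURATION_TIME_CITRINE = 29.0


def maturation_rate_from_time(t_mat: float) -> float:
    """Maturation half-time (min) to first-order rate (1/min), ln(2)/t."""
    if t_mat <= 0:
        raise ValueError("maturation time must be positive")
    return math.log(2) / t_mat


def hill_repression(x, ymin: float, K_M: float, n: float):
    """Repressive Hill law y = ymin + (1-ymin) K^n / (K^n + x^n).

    Evaluated as 1/(1 + (x/K)^n) for numerical range safety; negative x
    (which an unconstrained optimizer may probe) is clamped to zero.
    """
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    with np.errstate(over="ignore"):
        ratio = (x / K_M) ** n
    return ymin + (1.0 - ymin) / (1.0 + ratio)


@dataclass
class FluorescenceTrace:
    """Mature-reporter concentrations sampled at dilution-step boundaries."""

    times: np.ndarray       # min, uniform spacing dt
    Pf: np.ndarray          # nM
    dil: float              # volume fraction replaced per step
    dt: float               # min between steps
    mat: float              # 1/min
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.Pf = np.asarray(self.Pf, float)
        if self.times.shape != self.Pf.shape:
            raise ValueError("times and Pf must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.ptp(steps) > 1e-9 * self.dt or abs(steps[0] - self.dt) > 1e-9 * self.dt:
                raise ValueError("trace must be sampled uniformly at the step interval dt")
        if not 0 < self.dil < 1:
            raise ValueError("dil must lie in (0, 1)")
        if self.mat <= 0:
            raise ValueError("maturation rate must be positive")
        if np.any(self.Pf < 0):
            raise ValueError("fluorescent concentrations must be nonnegative")


def infer_dark_protein(trace: FluorescenceTrace) -> np.ndarray:
    """Dark-reporter series from fluorescence increments (length N-1).

    Negative inferred values (possible under measurement noise) are
    returned as-is; they are diagnostic, not fatal.
    """
    Pf = trace.Pf
    if Pf.size < 2:
        raise ValueError("need at least 2 samples to infer dark protein")
    return (Pf[1:] - Pf[:-1] + trace.dil * Pf[:-1]) / (trace.mat * trace.dt)


def infer_synthesis_rate(trace: FluorescenceTrace, Pd: np.ndarray | None = None) -> np.ndarray:
    """Synthesis-rate series from dark-pool increments (length N-2, nM/min)."""
    if Pd is None:
        Pd = infer_dark_protein(trace)
    Pd = np.asarray(Pd, float)
    if Pd.size < 2:
        raise ValueError("need at least 2 dark-protein values to infer synthesis")
    return (Pd[1:] - Pd[:-1] + trace.mat * Pd[:-1] * trace.dt
            + trace.dil * Pd[:-1]) / trace.dt


@dataclass
class TransferCurve:
    """Assembled (repressor, normalized synthesis) curve, descending branch."""

    x: np.ndarray                 # total repressor reporter, nM
    y: np.ndarray                 # synthesis rate / v_max
    v_max: float                  # nM/min
    x_err: float = MEASUREMENT_ERROR
    y_err: float = MEASUREMENT_ERROR
    branch: str = "descending"
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"repressor_nM": self.x, "norm_synthesis": self.y})


def _savgol(x: np.ndarray, window: int) -> np.ndarray:
    from scipy.signal import savgol_filter

    if window < 3 or x.size < window:
        return x
    return savgol_filter(x, window, polyorder=2)


def assemble_transfer_curve(promoter_trace: FluorescenceTrace,
                            repressor_trace: FluorescenceTrace,
                            min_repressor: float = MIN_REPRESSOR,
                            smooth: bool = True,
                            pf_window: int = 9,
                            pd_window: int = 7) -> TransferCurve:
    """Build a transfer curve from paired promoter/repressor reporter traces.

    x is the total repressor-reporter concentration (measured fluorescent
    plus inferred dark); y is the inferred promoter-reporter synthesis rate
    normalized to its maximum over the run (v_max).  Only the descending
    branch of the repressor profile (from its global maximum onward) and
    points with x above ``min_repressor`` are retained.  Negative inferred
    synthesis values are clipped to zero for the curve but preserved under
    ``diagnostics['raw_syn']``.

    With ``smooth`` (the default) the fluorescence traces are
    Savitzky-Golay filtered (quadratic, window ``pf_window`` steps) before
    differencing and the inferred dark series again (window ``pd_window``):
    the inversion is a double finite difference, so even small fast
    measurement noise is strongly amplified without smoothing.  v_max is
    then estimated as the median synthesis rate over the unrepressed
    samples (total repressor below ``min_repressor``), which is robust to
    slow calibration drift; taking the plain maximum over a drifting trace
    systematically overestimates v_max and biases K_M low.  Set
    ``smooth=False`` to apply the exact algebraic inversion with the plain
    maximum, appropriate for noiseless data.
    """
    pt, rt = promoter_trace, repressor_trace
    if pt.times.size != rt.times.size or np.max(np.abs(pt.times - rt.times)) > 1e-9:
        raise ValueError("promoter and repressor traces must share the same time base")
    if abs(pt.dt - rt.dt) > 1e-12 or abs(pt.dil - rt.dil) > 1e-12:
        raise ValueError("traces must share the same step interval and dilution fraction")

    if smooth:
        pt = FluorescenceTrace(pt.times, np.clip(_savgol(pt.Pf, pf_window), 0.0, None),
                               pt.dil, pt.dt, pt.mat, pt.label)
        rt = FluorescenceTrace(rt.times, np.clip(_savgol(rt.Pf, pf_window), 0.0, None),
                               rt.dil, rt.dt, rt.mat, rt.label)

    Pd_rep = infer_dark_protein(rt)
    Pd_pro = infer_dark_protein(pt)
    if smooth:
        Pd_rep = _savgol(Pd_rep, pd_window)
        Pd_pro = _savgol(Pd_pro, pd_window)
    total_rep = rt.Pf[:-1] + Pd_rep                       # length N-1
    syn = infer_synthesis_rate(pt, Pd_pro)                # length N-2
    x = total_rep[:-1]                                    # align with syn times
    unrepressed = x < min_repressor
    if smooth and np.count_nonzero(unrepressed) >= 5:
        v_max = float(np.median(syn[unrepressed]))
    elif smooth and syn.size >= 7:
        from scipy.ndimage import median_filter
        v_max = float(np.max(median_filter(syn, size=7, mode="nearest")))
    else:
        v_max = float(np.max(syn))
    if v_max <= 0:
        raise ValueError("no positive synthesis rate found; cannot normalize")
    y = np.clip(syn, 0.0, None) / v_max

    peak = int(np.argmax(x))                              # descending branch start
    keep = np.arange(peak, x.size)
    keep = keep[x[keep] > min_repressor]
    return TransferCurve(x=x[keep], y=y[keep], v_max=v_max,
                         diagnostics={"raw_syn": syn, "branch_start_index": peak,
                                      "total_repressor": total_rep})


class HillFitResults:
    """Fitted Hill-repression parameters with uncertainties.

    Attributes
    ----------
    params : dict
        ymin, K_M (nM) and n_hill point estimates.
    cov : ndarray
        3x3 covariance of (ymin, K_M, n_hill).
    bse : dict
        Standard errors.
    method : str
        'odr' (errors-in-variables) or 'wls' (fallback).
    """

    _names = ("ymin", "K_M", "n_hill")

    def __init__(self, beta, cov, method, curve, res_var=np.nan, note=""):
        self.params = dict(zip(self._names, (float(b) for b in beta)))
        self.cov = np.asarray(cov, float)
        self.bse = dict(zip(self._names, np.sqrt(np.diag(self.cov))))
        self.method = method
        self.curve = curve
        self.nobs = len(curve)
        self.res_var = float(res_var)
        self.note = note

    @property
    def ymin(self): return self.params["ymin"]

    @property
    def K_M(self): return self.params["K_M"]

    @property
    def n_hill(self): return self.params["n_hill"]

    def predict(self, x):
        return hill_repression(x, self.ymin, self.K_M, self.n_hill)

    def summary(self) -> str:
        lines = [
            "Hill transfer-function fit",
            "=" * 46,
            f"method: {self.method}   points: {self.nobs}   "
            f"res. var: {self.res_var:.4g}",
            f"v_max: {self.curve.v_max:.4g} nM/min (normalization)",
            "-" * 46,
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        units = {"ymin": "", "K_M": " nM", "n_hill": ""}
        for name in self._names:
            lines.append(f"{name:>8} {self.params[name]:>12.4g} "
                         f"{self.bse[name]:>12.3g}{units[name]}")
        if self.note:
            lines.append(f"note: {self.note}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<HillFitResults ymin={self.ymin:.3g} K_M={self.K_M:.3g} nM "
                f"n={self.n_hill:.3g} ({self.method})>")


class HillTransferModel:
    """Hill-repression model of a transfer curve; ``fit`` runs EIV regression.

    Construct from an assembled :class:`TransferCurve`, from paired traces
    (``from_traces``) or from a tidy table (``from_dataframe``).
    """

    #: fit bounds: K_M in (0, 10*max x], n in (0.3, 10], ymin in [0, 0.9]
    N_BOUNDS = (0.3, 10.0)
    YMIN_BOUNDS = (0.0, 0.9)

    def __init__(self, curve: TransferCurve):
        if len(curve) < 6:
            raise ValueError(f"need at least 6 curve points, got {len(curve)}")
        # K_M is identifiable only if the data cross the half-maximal region:
        # require the top plateau to be observed and the curve to drop below
        # ~half of the maximal rate within the measured repressor range.
        if np.max(curve.y) < 0.75 or np.min(curve.y) > 0.55:
            raise ValueError(
                "curve does not span both sides of half-maximal synthesis "
                f"(y range [{np.min(curve.y):.3g}, {np.max(curve.y):.3g}]); "
                "K_M may lie outside the measured repressor range")
        self.curve = curve

    @classmethod
    def from_traces(cls, promoter_trace: FluorescenceTrace,
                    repressor_trace: FluorescenceTrace, **kwargs) -> "HillTransferModel":
        return cls(assemble_transfer_curve(promoter_trace, repressor_trace, **kwargs))

    @classmethod
    def from_dataframe(cls, df, x_col: str = "repressor_nM",
                       y_col: str = "norm_synthesis", v_max: float = 1.0) -> "HillTransferModel":
        return cls(TransferCurve(x=df[x_col].to_numpy(float),
                                 y=df[y_col].to_numpy(float), v_max=v_max))

    def _start(self) -> np.ndarray:
        x, y = self.curve.x, self.curve.y
        ymin0 = max(float(np.min(y)), 0.0)
        yhalf = ymin0 + (1.0 - ymin0) / 2.0
        order = np.argsort(x)
        K0 = float(np.interp(yhalf, y[order][::-1], x[order][::-1]))
        if not np.isfinite(K0) or K0 <= 0:
            K0 = float(np.median(x))
        return np.array([min(ymin0, 0.89), K0, 2.0])

    def _in_bounds(self, beta) -> bool:
        ymin, K, n = beta
        return (self.YMIN_BOUNDS[0] <= ymin <= self.YMIN_BOUNDS[1]
                and 0.0 < K <= 10.0 * float(np.max(self.curve.x))
                and self.N_BOUNDS[0] < n <= self.N_BOUNDS[1])

    def fit(self, x_err: float | None = None, y_err: float | None = None) -> HillFitResults:
        """Errors-in-variables fit with relative errors on both coordinates.

        Defaults to the curve's stored 9% relative errors.  Falls back to
        bounded weighted least squares if the ODR solution is unusable.
        """
        import scipy.odr as odr

        curve = self.curve
        x, y = curve.x, curve.y
        x_err = curve.x_err if x_err is None else x_err
        y_err = curve.y_err if y_err is None else y_err
        beta0 = self._start()

        sx = x_err * x
        sy = y_err * np.maximum(y, 1e-3)   # floor keeps near-zero points finite-weighted
        model = odr.Model(lambda beta, xx: hill_repression(xx, *beta))
        data = odr.RealData(x, y, sx=sx, sy=sy)
        out = odr.ODR(data, model, beta0=beta0, maxit=200).run()
        converged = out.info in (1, 2, 3) and np.all(np.isfinite(out.beta))
        if converged and self._in_bounds(out.beta):
            return HillFitResults(out.beta, out.cov_beta * out.res_var,
                                  "odr", curve, res_var=out.res_var)
        return self._fit_wls(beta0, y_err, note="ODR solution rejected; "
                             "weighted least squares fallback")

    def _fit_wls(self, beta0, y_err, note="") -> HillFitResults:
        from scipy.optimize import least_squares

        x, y = self.curve.x, self.curve.y
        sy = y_err * np.maximum(y, 1e-3)
        lo = [self.YMIN_BOUNDS[0], 1e-12, self.N_BOUNDS[0] + 1e-9]
        hi_ = [self.YMIN_BOUNDS[1], 10.0 * float(np.max(x)), self.N_BOUNDS[1]]
        beta0 = np.clip(beta0, lo, hi_)
        res = least_squares(lambda b: (hill_repression(x, *b) - y) / sy,
                            beta0, bounds=(lo, hi_))
        dof = max(x.size - 3, 1)
        res_var = 2.0 * res.cost / dof
        JTJ = res.jac.T @ res.jac
        cov = np.linalg.pinv(JTJ) * res_var
        return HillFitResults(res.x, cov, "wls", self.curve,
                              res_var=res_var, note=note)


def fit_hill(curve: TransferCurve, x_err: float | None = None,
             y_err: float | None = None) -> HillFitResults:
    """Convenience wrapper: ``HillTransferModel(curve).fit()``."""
    return HillTransferModel(curve).fit(x_err=x_err, y_err=y_err)


def normalize_vmax(vmax_table: dict, reference: str) -> dict:
    """Divide all promoter v_max values by the reference promoter's."""
    if reference not in vmax_table:
        raise KeyError(f"reference promoter {reference!r} not in table")
    ref = vmax_table[reference]
    if ref == 0:
        raise ValueError("reference v_max must be nonzero")
    return {k: v / ref for k, v in vmax_table.items()}
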