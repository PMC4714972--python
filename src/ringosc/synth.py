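"""Synthetic reactor experiments with known ground truth.

Every generator returns the noiseless truth alongside the data so that the
inference modules can be tested end to end without any external
measurements.

Noise model.  Fluorescence measurement error is multiplicative lognormal
(it scales with signal) with a default coefficient of variation of 0.09,
matching the relative measurement error assumed by the fitting stage.  The
dominant part of that error is calibration uncertainty -- the conversion
from fluorescence to absolute concentration -- which drifts slowly over a
run rather than resampling independently at every dilution step; it is
modeled as a lognormal AR(1) process in log space with a correlation time
of 480 min.  A small fast photometric component (CV = noise_cv / 9, so 1%
at the default) is superimposed per sample.  Rapid step-to-step
measurement noise at the full 9% would be physically implausible and would
make any finite-difference synthesis-rate inversion meaningless, since
each differencing stage amplifies white noise by roughly 1/(mat*dt) and
1/dil.  All randomness flows from the per-spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReactorSettings, RingNetwork, RingState
from .simulate import simulate
from .transfer import (MATURATION_TIME_CERULEAN, MATURATION_TIME_CITRINE,
                       FluorescenceTrace, hill_repression,
                       maturation_rate_from_time)

__all__ = ["SynthSpec", "gen_reactor_trace", "gen_transfer_experiment",
           "gen_oscillator_trace"]


@dataclass
class SynthSpec:
    """Conditions of a synthetic reactor run.

    Defaults mirror the device protocol: a dilution step replacing 15% of
    the reactor volume every 8 min, a repressor-template ramp from 0 to
    2.5 nM and back over the run, maturation rates from the measured
    15 min (repressor reporter) and 29 min (promoter reporter) maturation
    times, and 9% multiplicative measurement noise.
    """

    seed: int = 0
    noise_cv: float = 0.09
    noise_corr_min: float = 480.0         # correlation time of calibration drift
    point_noise_cv: float | None = None   # fast component; defaults to noise_cv/9
    dil: float = 0.15
    dt: float = 8.0                       # min between dilution steps
    mat_repressor: float = field(default_factory=lambda: maturation_rate_from_time(MATURATION_TIME_CERULEAN))
    mat_promoter: float = field(default_factory=lambda: maturation_rate_from_time(MATURATION_TIME_CITRINE))
    n_steps: int = 180                    # 24 h at dt = 8 min
    ramp_peak: float = 2.5                # nM template at mid-run
    truth: dict | None = None             # Hill law {ymin, K_M, n, v_max}

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.point_noise_cv is None:
            self.point_noise_cv = self.noise_cv / 9.0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + salt)

    def noise_factors(self, n: int, dt: float, salt: int = 0) -> np.ndarray:
        """Multiplicative lognormal measurement-noise series of length n.

        Unit mean; slowly drifting calibration component (CV ``noise_cv``,
        AR(1) in log space with correlation time ``noise_corr_min``) times
        an iid photometric component (CV ``point_noise_cv``).  Returns all
        ones when ``noise_cv`` is zero.
        """
        if self.noise_cv == 0:
            return np.ones(n)
        rng = self.rng(salt)
        sig = np.sqrt(np.log1p(self.noise_cv ** 2))
        rho = np.exp(-dt / self.noise_corr_min)
        z = np.empty(n)
        z[0] = rng.standard_normal()
        innov = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
        for t in range(1, n):
            z[t] = rho * z[t - 1] + np.sqrt(1.0 - rho * rho) * innov[t - 1]
        drift = np.exp(sig * z - 0.5 * sig ** 2)
        sp = np.sqrt(np.log1p(self.point_noise_cv ** 2))
        point = np.exp(sp * rng.standard_normal(n) - 0.5 * sp ** 2)
        return drift * point


def _forward_recursion(syn: np.ndarray, dil: float, dt: float, mat: float):
    """Iterate the dark/fluorescent step recursion from zero initial pools."""
    n = syn.size + 1
    Pd = np.zeros(n)
    Pf = np.zeros(n)
    for t in range(n - 1):
        Pd[t + 1] = Pd[t] + syn[t] * dt - mat * Pd[t] * dt - dil * Pd[t]
        Pf[t + 1] = Pf[t] + mat * Pd[t] * dt - dil * Pf[t]
    return Pd, Pf


def gen_reactor_trace(spec: SynthSpec, syn_profile: np.ndarray,
                      mat: float | None = None, label: str = "reporter",
                      salt: int = 0) -> tuple[FluorescenceTrace, dict]:
    """Render a synthesis-rate profile into a noisy fluorescence trace.

    ``syn_profile`` gives the synthesis rate (nM/min) at each step; the
    returned trace has one more sample than the profile.  The hidden-truth
    record carries the noiseless dark and fluorescent series and the input
    profile.
    """
    syn = np.asarray(syn_profile, float)
    mat = spec.mat_promoter if mat is None else mat
    Pd, Pf = _forward_recursion(syn, spec.dil, spec.dt, mat)
    times = np.arange(Pf.size) * spec.dt
    Pf_noisy = Pf * spec.noise_factors(Pf.size, spec.dt, salt=salt)
    trace = FluorescenceTrace(times=times, Pf=Pf_noisy, dil=spec.dil,
                              dt=spec.dt, mat=mat, label=label)
    truth = {"Pd": Pd, "Pf": Pf, "syn": syn}
    return trace, truth


def template_ramp(spec: SynthSpec) -> np.ndarray:
    """Template profile 0 -> ramp_peak -> 0 nM over the run.

    Rises over the first 40% of the run, falls over the next 40%, and
    stays at zero for the final 20% so that the repressor washes out and
    the descending branch of the transfer curve reaches its unrepressed
    plateau before the run ends.
    """
    up_n = int(0.4 * spec.n_steps)
    down_n = int(0.4 * spec.n_steps)
    tail_n = spec.n_steps - up_n - down_n
    up = np.linspace(0.0, spec.ramp_peak, up_n, endpoint=False)
    down = np.linspace(spec.ramp_peak, 0.0, down_n)
    return np.concatenate([up, down, np.zeros(tail_n)])


def gen_transfer_experiment(spec: SynthSpec) -> tuple[FluorescenceTrace, FluorescenceTrace, dict]:
    """Paired promoter/repressor reporter traces from a known Hill truth.

    The repressor (and its co-expressed reporter) is synthesized in
    proportion to the template ramp; the per-nM expression rate is
    calibrated so the peak template drives the repressor to about ten times
    the truth's K_M, guaranteeing curve coverage.  The promoter reporter is
    synthesized at ``v_max * Hill(repressor)`` evaluated on the noiseless
    total repressor concentration.
    """
    if not spec.truth:
        raise ValueError("spec.truth must provide the Hill law "
                         "{ymin, K_M, n, v_max}")
    truth = dict(spec.truth)
    truth.setdefault("v_max", 1.0)
    ramp = template_ramp(spec)
    # per-nM-template expression rate, calibrated once against the standard
    # 2.5 nM protocol so that the full ramp drives the repressor to ~10 K_M;
    # steady-state repressor under syn = k_expr * template is R* = syn*dt/dil
    k_expr = 10.0 * truth["K_M"] * spec.dil / (spec.dt * 2.5)
    syn_rep = k_expr * ramp
    rep_trace, rep_truth = gen_reactor_trace(
        spec, syn_rep, mat=spec.mat_repressor, label="repressor_reporter", salt=1)
    total_repressor = rep_truth["Pd"] + rep_truth["Pf"]
    syn_prom = truth["v_max"] * hill_repression(
        total_repressor[:-1], truth["ymin"], truth["K_M"], truth["n"])
    prom_trace, prom_truth = gen_reactor_trace(
        spec, syn_prom, mat=spec.mat_promoter, label="promoter_reporter", salt=2)
    hidden = {"hill": truth, "template_nM": ramp, "k_expr": k_expr,
              "total_repressor": total_repressor,
              "repressor": rep_truth, "promoter": prom_truth}
    return prom_trace, rep_trace, hidden


def gen_oscillator_trace(net: RingNetwork, reactor: ReactorSettings,
                         spec: SynthSpec, species: str = "p1",
                         init: RingState | None = None,
                         horizon: float | None = None,
                         sampling: float | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate a ring and overlay multiplicative measurement noise.

    Returns (times, noisy signal, truth) where truth carries the noiseless
    trajectory; used to exercise the period estimators under realistic
    noise.
    """
    if init is None:
        init = RingState.pulse(net.n)
    traj = simulate(net, reactor, init, horizon=horizon, sampling=sampling)
    clean = traj.species(species)
    dt = float(traj.times[1] - traj.times[0])
    noisy = clean * spec.noise_factors(clean.size, dt)
    return traj.times, noisy, {"trajectory": traj, "species": species}
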