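"""Closed-form oscillation-existence conditions and regime maps.

For the symmetric n-node ring (identical nodes), the equilibrium is unique
and the protein concentrations oscillate when both of the following hold:

    (i)   nu > W(n, Q)
    (ii)  c * beta * g > (W/(nu-W))^(1/nu) * (nu/(nu-W)) * K (a+mu)(b+mu)

where

    W(n, Q) = 2 (-cos(pi/n) + sqrt(cos^2(pi/n) + Q^2 sin^2(pi/n)))
              / (Q^2 sin^2(pi/n)),
    Q       = sqrt((a+mu)(b+mu)) / ((a+b+2mu)/2),

i.e. Q is the geometric-to-arithmetic mean ratio of the two effective
decay rates (so 0 < Q <= 1, with Q = 1 iff a = b).  At Q = 1, W reduces
to the classical secant-criterion bound 2/(1 + cos(pi/n)).  Condition (i)
depends only on n and the decay rates; condition (ii) compares the maximal
protein synthesis flux c*beta*g against a threshold set by K and the decay
rates.  The left side of (ii) uses beta*g because the model's maximal
transcription rate is beta*g (beta is per nM of plasmid template).

Asymmetric rings fall outside the closed form and are classified by the
Jacobian eigenvalues at the unique equilibrium: the ring oscillates iff an
eigenvalue lies in the open right-half complex plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import RingNetwork, find_equilibrium

__all__ = [
    "compute_Q",
    "compute_W",
    "check_conditions",
    "ConditionReport",
    "RegimeMap",
    "regime_map_td_synthesis",
    "regime_map_K_td",
]


def compute_Q(a: float, b: float, mu: float) -> float:
    """Geometric over arithmetic mean of the effective decay rates a+mu, b+mu."""
    x, y = a + mu, b + mu
    if x <= 0 or y <= 0:
        raise ValueError("effective decay rates must be positive")
    return math.sqrt(x * y) / ((x + y) / 2.0)


def compute_W(n: int, Q: float) -> float:
    """The Hill-coefficient threshold W(n, Q) for the symmetric n-ring."""
    if n < 2:
        raise ValueError("need n >= 2")
    if Q <= 0:
        raise ValueError("W(n, Q) is unbounded as Q -> 0; need Q > 0")
    if Q > 1:
        raise ValueError(f"Q must lie in (0, 1], got {Q}")
    c, s2 = math.cos(math.pi / n), math.sin(math.pi / n) ** 2
    return 2.0 * (-c + math.sqrt(c * c + Q * Q * s2)) / (Q * Q * s2)


@dataclass
class ConditionReport:
    """Evaluation of the two closed-form oscillation conditions."""

    Q: float
    W: float
    cond9: bool
    margin9: float            # nu - W; positive when cond9 holds
    cond10: bool
    margin10: float | None    # c*beta*g - threshold (nM/min^2); None if cond9 fails
    oscillatory: bool
    params: dict = field(default_factory=dict)
    reason: str = ""


def check_conditions(net: RingNetwork, mu: float) -> ConditionReport:
    """Evaluate conditions (i) and (ii) for a symmetric ring at dilution rate mu."""
    if not net.is_symmetric:
        raise ValueError("closed-form conditions apply to symmetric rings only; "
                         "use the Jacobian eigenvalue route for asymmetric networks")
    a, b, c, beta = net.a[0], net.b[0], net.c[0], net.beta[0]
    K, nu, g, n = net.K[0], net.nu[0], net.g, net.n
    Q = compute_Q(a, b, mu)
    W = compute_W(n, Q)
    margin9 = nu - W
    cond9 = margin9 > 0
    params = dict(a=a, b=b, c=c, beta=beta, K=K, nu=nu, g=g, mu=mu, n=n)
    if not cond9:
        return ConditionReport(Q, W, False, margin9, False, None, False,
                               params, reason="cond9 failed (threshold undefined)")
    threshold = ((W / (nu - W)) ** (1.0 / nu) * (nu / (nu - W))
                 * K * (a + mu) * (b + mu))
    lhs = c * beta * g
    margin10 = lhs - threshold
    cond10 = margin10 > 0
    return ConditionReport(Q, W, cond9, margin9, cond10, margin10,
                           cond9 and cond10, params)


@dataclass
class RegimeMap:
    """Boolean (or ternary) oscillation map over a parameter grid.

    ``values`` uses 1 = oscillatory, 0 = stable, -1 = indeterminate.
    ``axes`` maps axis names to their grids, in array-dimension order.
    """

    axes: dict
    values: np.ndarray
    method: str

    def __post_init__(self):
        shape = tuple(len(v) for v in self.axes.values())
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {shape}")


def regime_map_td_synthesis(net: RingNetwork, t_d_grid, tx_scales, tl_scales) -> RegimeMap:
    """Closed-form oscillation map over dilution time and synthesis-rate scalings.

    ``tx_scales`` multiplies the transcription rate beta, ``tl_scales`` the
    translation rate c.  Returns a (t_d, tx, tl) boolean map.
    """
    t_d_grid = np.asarray(t_d_grid, float)
    tx_scales = np.asarray(tx_scales, float)
    tl_scales = np.asarray(tl_scales, float)
    if np.any(tx_scales < 0) or np.any(tl_scales < 0):
        raise ValueError("synthesis scalings must be nonnegative")
    vals = np.zeros((t_d_grid.size, tx_scales.size, tl_scales.size), dtype=np.int8)
    for i, t_d in enumerate(t_d_grid):
        mu = math.log(2) / t_d
        for j, sx in enumerate(tx_scales):
            for k, sl in enumerate(tl_scales):
                if sx == 0.0 or sl == 0.0:
                    continue
                scaled = net.replace(beta=net.beta * sx, c=net.c * sl)
                vals[i, j, k] = int(check_conditions(scaled, mu).oscillatory)
    return RegimeMap(axes={"t_d_min": t_d_grid, "tx_scale": tx_scales,
                           "tl_scale": tl_scales},
                     values=vals, method="analytic")


def regime_map_K_td(net: RingNetwork, K_index: int, K_grid, t_d_grid) -> RegimeMap:
    """Eigenvalue-based oscillation map over one node's K and the dilution time.

    For each grid cell the unique equilibrium is located and the ring is
    marked oscillatory iff the Jacobian there has an eigenvalue with
    positive real part.  Equilibrium failures are marked indeterminate
    (-1), never silently oscillatory.
    """
    if not 0 <= K_index < net.n:
        raise IndexError(f"K_index {K_index} out of range for n={net.n}")
    K_grid = np.asarray(K_grid, float)
    t_d_grid = np.asarray(t_d_grid, float)
    vals = np.zeros((K_grid.size, t_d_grid.size), dtype=np.int8)
    for i, Kv in enumerate(K_grid):
        varied = net.with_node_param("K", K_index, float(Kv))
        for j, t_d in enumerate(t_d_grid):
            mu = math.log(2) / t_d
            try:
                eq = find_equilibrium(varied, mu)
            except RuntimeError:
                vals[i, j] = -1
                continue
            vals[i, j] = int(np.max(eq.eigenvalues.real) > 0)
    return RegimeMap(axes={"K_nM": K_grid, "t_d_min": t_d_grid},
                     values=vals, method="eigenvalue")
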