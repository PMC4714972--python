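"""n-node cyclic-repression networks: rate laws, equilibria, Jacobian.

The model is an n-gene ring in which protein :math:`P_{i-1}` represses
transcription of gene :math:`G_i` through a Hill function, with all species
diluted at rate ``mu`` (the reactor dilution rate, the analogue of cellular
growth dilution)::

    dr_i/dt = -(a_i + mu) r_i + beta_i g K_{i-1}^nu_i / (K_{i-1}^nu_i + p_{i-1}^nu_i)
    dp_i/dt = -(b_i + mu) p_i + c_i r_i

with cyclic indexing (node 0 == node n).  Units are nM and minutes
throughout.  ``a``/``b`` are mRNA/protein degradation rates (1/min), ``c``
the translation rate per unit mRNA, ``beta`` the transcription rate per nM
plasmid, ``K`` the half-repression constant of protein P_i acting on gene
G_{i+1}, ``nu`` the Hill coefficient, and ``g`` the plasmid concentration.

Wiring convention (n = 3)::

    P_3 --| G_1 -> P_1 --| G_2 -> P_2 --| G_3 -> P_3

i.e. the repressor of gene G_i is protein P_{i-1}; the repression constant
applied to gene G_i is K_{i-1}.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingNetwork",
    "RingState",
    "ReactorSettings",
    "EquilibriumResult",
    "dilution_rate_from_time",
    "dilution_time_from_rate",
    "ode_rhs",
    "jacobian",
    "find_equilibrium",
    "find_all_equilibria",
]

# Default kinetic parameters (nM, min): mRNA half-life 8 min, protein
# half-life 90 min (ssrA-tagged), transcription 0.4 nM/min per nM plasmid,
# translation 0.5 /min, K = 5 nM, Hill coefficient 2, plasmid 5 nM.
DEFAULT_A = math.log(2) / 8.0
DEFAULT_B = math.log(2) / 90.0
DEFAULT_C = 0.5
DEFAULT_BETA = 0.4
DEFAULT_K = 5.0
DEFAULT_NU = 2.0
DEFAULT_G = 5.0


def dilution_rate_from_time(t_d: float) -> float:
    """Convert a dilution time (min) to a dilution rate mu = ln(2)/t_d (1/min)."""
    if t_d <= 0:
        raise ValueError(f"dilution time must be positive, got {t_d}")
    return math.log(2) / t_d


def dilution_time_from_rate(mu: float) -> float:
    """Convert a dilution rate (1/min) to the dilution time t_d = ln(2)/mu (min)."""
    if mu <= 0:
        raise ValueError(f"dilution rate must be positive, got {mu}")
    return math.log(2) / mu


def _as_vector(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"parameter '{name}' must be scalar or length-{n}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RingNetwork:
    """Full parameterization of an n-node repression ring.

    Scalar parameter values are broadcast to all n nodes.
    """

    n: int
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    beta: np.ndarray
    K: np.ndarray
    nu: np.ndarray
    g: float = DEFAULT_G
    name: str = "ring"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"need at least 2 nodes, got n={self.n}")
        for attr in ("a", "b", "c", "beta", "K", "nu"):
            object.__setattr__(self, attr, _as_vector(getattr(self, attr), self.n, attr))
        if np.any(self.a <= 0) or np.any(self.c <= 0) or np.any(self.beta <= 0) or np.any(self.K <= 0):
            raise ValueError("a, c, beta, K must be strictly positive")
        if np.any(self.b < 0):
            raise ValueError("protein degradation rate b must be nonnegative")
        if np.any(self.nu < 1):
            raise ValueError("Hill coefficient nu must be >= 1")
        if self.g < 0:
            raise ValueError("plasmid concentration g must be nonnegative")

    @classmethod
    def symmetric(cls, n: int, a: float = DEFAULT_A, b: float = DEFAULT_B,
                  c: float = DEFAULT_C, beta: float = DEFAULT_BETA,
                  K: float = DEFAULT_K, nu: float = DEFAULT_NU,
                  g: float = DEFAULT_G, name: str = "ring") -> "RingNetwork":
        """Identical-node ring with the default simulation parameters."""
        return cls(n=n, a=a, b=b, c=c, beta=beta, K=K, nu=nu, g=g, name=name)

    @property
    def is_symmetric(self) -> bool:
        return all(np.ptp(getattr(self, attr)) == 0.0
                   for attr in ("a", "b", "c", "beta", "K", "nu"))

    def replace(self, **kwargs) -> "RingNetwork":
        """Return a copy with some fields replaced (numpy-safe dataclasses.replace)."""
        return dataclasses.replace(self, **kwargs)

    def with_node_param(self, attr: str, index: int, value: float) -> "RingNetwork":
        """Return a copy with one node's parameter changed (0-based index)."""
        vec = getattr(self, attr).copy()
        vec[index] = value
        return self.replace(**{attr: vec})


@dataclass
class RingState:
    """mRNA (r) and protein (p) concentration vectors, nM, length n."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.r.shape != self.p.shape:
            raise ValueError("r and p must have the same length")
        if np.any(self.r < 0) or np.any(self.p < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def n(self) -> int:
        return self.r.size

    def to_flat(self) -> np.ndarray:
        """Flatten to (r_1..r_n, p_1..p_n) ordering."""
        return np.concatenate([self.r, self.p])

    @classmethod
    def from_flat(cls, y: np.ndarray) -> "RingState":
        y = np.asarray(y, dtype=float)
        n = y.size // 2
        return cls(r=y[:n], p=y[n:])

    @classmethod
    def zeros(cls, n: int) -> "RingState":
        return cls(r=np.zeros(n), p=np.zeros(n))

    @classmethod
    def pulse(cls, n: int, r1: float = 30.0) -> "RingState":
        """The standard simulation initial condition: r_1 = 30 nM, all else 0."""
        r = np.zeros(n)
        r[0] = r1
        return cls(r=r, p=np.zeros(n))


@dataclass(frozen=True)
class ReactorSettings:
    """Dilution protocol of the nano-reactor.

    ``continuous`` mode dilutes all species at rate ``mu`` inside the ODE;
    ``discrete`` mode emulates the device protocol of exchanging a fixed
    volume fraction every ``step_interval`` minutes.  In discrete mode the
    continuous-equivalent rate -ln(1-step_fraction)/step_interval is exposed
    as ``effective_rate``.
    """

    mu: float
    mode: str = "continuous"
    step_fraction: float = 0.15
    step_interval: float = 8.0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("dilution rate mu must be positive")
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"mode must be 'continuous' or 'discrete', got {self.mode!r}")
        if not 0 < self.step_fraction < 1:
            raise ValueError("step_fraction must lie in (0, 1)")
        if self.step_interval <= 0:
            raise ValueError("step_interval must be positive")

    @classmethod
    def from_dilution_time(cls, t_d: float, **kwargs) -> "ReactorSettings":
        return cls(mu=dilution_rate_from_time(t_d), **kwargs)

    @classmethod
    def discrete_steps(cls, step_fraction: float, step_interval: float) -> "ReactorSettings":
        """Discrete protocol with mu set to the continuous-equivalent rate."""
        mu = -math.log(1.0 - step_fraction) / step_interval
        return cls(mu=mu, mode="discrete",
                   step_fraction=step_fraction, step_interval=step_interval)

    @property
    def dilution_time(self) -> float:
        return dilution_time_from_rate(self.mu)

    @property
    def effective_rate(self) -> float:
        """Continuous-equivalent rate of the discrete protocol (1/min)."""
        return -math.log(1.0 - self.step_fraction) / self.step_interval


@dataclass
class EquilibriumResult:
    """A fixed point of the ring ODE with its local stability."""

    state: RingState
    residual: float
    eigenvalues: np.ndarray
    stable: bool


def _hill(p_prev: np.ndarray, K_prev: np.ndarray, nu: np.ndarray) -> np.ndarray:
    # K_prev^nu / (K_prev^nu + p_prev^nu), computed as 1/(1+(p/K)^nu) for stability
    with np.errstate(divide="ignore"):
        ratio = np.where(p_prev > 0, (p_prev / K_prev), 0.0)
    return 1.0 / (1.0 + ratio ** nu)


def ode_rhs(net: RingNetwork, state: RingState, mu: float) -> RingState:
    """Deterministic rate laws of the repression ring (nM/min)."""
    if state.n != net.n:
        raise ValueError(f"state has {state.n} nodes, network has {net.n}")
    dr, dp = _rhs_vectors(net, state.r, state.p, mu)
    out = RingState.__new__(RingState)   # skip nonnegativity check: derivatives may be < 0
    out.r, out.p = dr, dp
    return out


def _rhs_vectors(net: RingNetwork, r: np.ndarray, p: np.ndarray, mu: float):
    p_prev = np.roll(p, 1)
    K_prev = np.roll(net.K, 1)
    dr = -(net.a + mu) * r + net.beta * net.g * _hill(p_prev, K_prev, net.nu)
    dp = -(net.b + mu) * p + net.c * r
    return dr, dp


def rhs_flat(net: RingNetwork, y: np.ndarray, mu: float) -> np.ndarray:
    """ODE right-hand side on the flat (r_1..r_n, p_1..p_n) vector."""
    n = net.n
    dr, dp = _rhs_vectors(net, y[:n], y[n:], mu)
    return np.concatenate([dr, dp])


def jacobian(net: RingNetwork, state: RingState, mu: float) -> np.ndarray:
    """Analytic Jacobian of the ring ODE, 2n x 2n, in (r, p) block ordering.

    Row/column order is (r_1..r_n, p_1..p_n).  Nonzero entries: the decay
    diagonals -(a_i+mu), -(b_i+mu); translation dp_i/dr_i = c_i; and the
    repression coupling d(dr_i)/d(p_{i-1}) = -beta_i g nu_i K^nu p^(nu-1) /
    (K^nu + p^nu)^2 evaluated at K = K_{i-1}, p = p_{i-1}.
    """
    if state.n != net.n:
        raise ValueError(f"state has {state.n} nodes, network has {net.n}")
    return jacobian_flat(net, state.to_flat(), mu)


def jacobian_flat(net: RingNetwork, y: np.ndarray, mu: float) -> np.ndarray:
    n = net.n
    p = y[n:]
    p_prev = np.roll(p, 1)
    K_prev = np.roll(net.K, 1)
    J = np.zeros((2 * n, 2 * n))
    J[np.arange(n), np.arange(n)] = -(net.a + mu)
    J[np.arange(n, 2 * n), np.arange(n, 2 * n)] = -(net.b + mu)
    J[np.arange(n, 2 * n), np.arange(n)] = net.c
    # d/dp of K^nu/(K^nu+p^nu) = -nu K^nu p^(nu-1)/(K^nu+p^nu)^2; zero at p=0 for nu>1
    Kp = K_prev ** net.nu
    with np.errstate(invalid="ignore"):
        pp = np.where(p_prev > 0, p_prev ** (net.nu - 1.0), np.where(net.nu == 1.0, 1.0, 0.0))
    dhill = -net.nu * Kp * pp / (Kp + np.where(p_prev > 0, p_prev ** net.nu, 0.0)) ** 2
    prev_idx = (np.arange(n) - 1) % n
    J[np.arange(n), n + prev_idx] = net.beta * net.g * dhill
    return J


# ---------------------------------------------------------------------------
# Equilibria via one-dimensional reduction around the loop
# ---------------------------------------------------------------------------

def _node_map(net: RingNetwork, mu: float, i: int, p_prev: float) -> float:
    """Steady-state protein of node i given its repressor concentration."""
    K = net.K[(i - 1) % net.n]
    hill = 1.0 / (1.0 + (p_prev / K) ** net.nu[i]) if p_prev > 0 else 1.0
    r = net.beta[i] * net.g * hill / (net.a[i] + mu)
    return net.c[i] * r / (net.b[i] + mu)


def _loop_map(net: RingNetwork, mu: float, p_n: float) -> float:
    """Compose the node maps once around the ring, starting from p_n."""
    x = p_n
    for i in range(net.n):
        x = _node_map(net, mu, i, x)
    return x


def _state_from_pn(net: RingNetwork, mu: float, p_n: float) -> RingState:
    r = np.empty(net.n)
    p = np.empty(net.n)
    x = p_n
    for i in range(net.n):
        K = net.K[(i - 1) % net.n]
        hill = 1.0 / (1.0 + (x / K) ** net.nu[i]) if x > 0 else 1.0
        r[i] = net.beta[i] * net.g * hill / (net.a[i] + mu)
        p[i] = net.c[i] * r[i] / (net.b[i] + mu)
        x = p[i]
    return RingState(r=np.maximum(r, 0.0), p=np.maximum(p, 0.0))


def _equilibrium_from_pn(net: RingNetwork, mu: float, p_n: float) -> EquilibriumResult:
    state = _state_from_pn(net, mu, p_n)
    deriv = ode_rhs(net, state, mu)
    residual = float(max(np.max(np.abs(deriv.r)), np.max(np.abs(deriv.p))))
    eig = np.linalg.eigvals(jacobian(net, state, mu))
    return EquilibriumResult(state=state, residual=residual,
                             eigenvalues=eig, stable=bool(np.max(eig.real) < 0))


def _p_max(net: RingNetwork, mu: float) -> float:
    """Upper bound on any steady-state protein: repression-free production."""
    return float(np.max(net.c * net.beta * net.g / ((net.a + mu) * (net.b + mu))))


def find_equilibrium(net: RingNetwork, mu: float) -> EquilibriumResult:
    """Locate the equilibrium of the ring by a 1-D fixed point of the loop map.

    The 2n-dimensional fixed-point problem reduces to ``Phi(p_n) = p_n``
    where ``Phi`` composes the monotone-decreasing single-node steady-state
    maps around the loop.  For odd n, ``Phi`` is decreasing so the root is
    unique and bracketed in [0, p_max]; for even rings with several fixed
    points this returns the one found by bisection from that bracket (use
    :func:`find_all_equilibria` to enumerate them).
    """
    from scipy.optimize import brentq

    if net.g == 0:
        return _equilibrium_from_pn(net, mu, 0.0)
    hi = _p_max(net, mu) * (1.0 + 1e-9) + 1e-12
    f = lambda x: _loop_map(net, mu, x) - x
    f0 = f(0.0)
    if f0 <= 0.0:   # no production reaching node n: origin-side root
        return _equilibrium_from_pn(net, mu, 0.0 if f0 == 0.0 else brentq(f, 0.0, hi, xtol=1e-14))
    fhi = f(hi)
    if fhi > 0.0:
        raise RuntimeError(
            f"equilibrium bracketing failed: f(0)={f0:.3g}, f({hi:.3g})={fhi:.3g}")
    root = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    return _equilibrium_from_pn(net, mu, root)


def find_all_equilibria(net: RingNetwork, mu: float, grid_size: int = 600) -> list[EquilibriumResult]:
    """Enumerate all fixed points of the loop map by a sign-change scan.

    Odd rings have a single equilibrium; even rings (e.g. the 4-node
    switch) can have up to three, two of them stable.  The scan brackets
    every sign change of ``Phi(x) - x`` on a dense grid over [0, p_max]
    and refines each bracket with Brent's method.
    """
    from scipy.optimize import brentq

    if net.g == 0:
        return [_equilibrium_from_pn(net, mu, 0.0)]
    hi = _p_max(net, mu) * (1.0 + 1e-9) + 1e-12
    xs = np.linspace(0.0, hi, grid_size)
    f = np.array([_loop_map(net, mu, x) - x for x in xs])
    roots: list[float] = []
    for k in range(grid_size - 1):
        if f[k] == 0.0:
            roots.append(xs[k])
        elif f[k] * f[k + 1] < 0.0:
            roots.append(brentq(lambda x: _loop_map(net, mu, x) - x,
                                xs[k], xs[k + 1], xtol=1e-14, rtol=8.9e-16))
    if f[-1] == 0.0:
        roots.append(xs[-1])
    # collapse near-duplicates from grid ties
    dedup: list[float] = []
    for r in roots:
        if not any(abs(r - q) < 1e-9 * (1.0 + hi) for q in dedup):
            dedup.append(r)
    return [_equilibrium_from_pn(net, mu, r) for r in dedup]
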