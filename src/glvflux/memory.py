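"""History-weighted trophic functionals and the memory-free (Dirac) limit.

The trophic functional of species i under a family of measures mu_t on [0, t]
is the time-normalized history average

    tau_i(t) = (1/t) * int_0^t p_i(s, N(s), cumN(s)) N_i(s) d mu_t(s),

where p_i = mbar_i * k_i is the effective trophic potential per individual
(the product of mean individual biomass and relative trophic strength; the
model only ever uses the product, so only p is housed). Two measure families
are supported:

* density kind: d mu_t(s) = w_t(s) ds with w(t, t) > 0, e.g. the Gaussian
  kernel w_t(s) = exp(-a (s - t)^2) — recent history weighs more;
* dirac kind: mu_t = t * delta(t - s), the memory-free limit, for which
  tau_i(t) = p_i(t) N_i(t) exactly (the 1/t prefactor cancels the mass t).

The total time derivative of the density-kind functional is

    d tau_i/dt = -(1/t^2) int_0^t f_i w_t ds
                 + (1/t) [ f_i(t) w_t(t) + int_0^t f_i dw_t/dt ds ],

with f_i(s) = p_i(s) N_i(s). All quadrature is composite trapezoid on the
trajectory's own output grid, so the trophic and flux series share one error
budget; a ``quad_refine`` knob optionally inserts cubic-interpolated
midpoints to shrink the trapezoid step without re-integrating the ODE.

The module also provides the Picard-iteration oracle for the Volterra
integral equation phi(t) = int_0^t phi(s) K(t, s) ds, whose unique continuous
solution is trivial; the decay of the iterate sup-norms is the numerical
counterpart of the uniqueness argument behind the memory-equilibrium
dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .glv import Trajectory

__all__ = [
    "MemoryMeasure",
    "TrophicWeights",
    "TrophicSeries",
    "WeightBoundReport",
    "gaussian_measure",
    "dirac_measure",
    "density_measure",
    "constant_weights",
    "trophic_functional",
    "trophic_derivative",
    "trophic_series",
    "check_weight_bound",
    "volterra_trivial_check",
]

# Finite-difference step rule for numerically differentiated kernels/weights.
_FD_STEP = lambda t: 1e-6 * (1.0 + abs(t))


@dataclass(frozen=True)
class MemoryMeasure:
    """The family mu_t weighting past states.

    kind is "density" (w, dw_dt callables of (t, s), numpy-vectorized in s)
    or "dirac" (mu_t = t * delta(t - s); no parameters). ``dw_dt_numeric``
    flags a finite-difference fallback for a user kernel supplied without an
    analytic time derivative.
    """

    kind: str
    w: Callable[[float, np.ndarray], np.ndarray] | None = None
    dw_dt: Callable[[float, np.ndarray], np.ndarray] | None = None
    params: dict | None = None
    dw_dt_numeric: bool = False

    def __post_init__(self):
        if self.kind not in ("density", "dirac"):
            raise ValueError(f"unknown measure kind {self.kind!r}")
        if self.kind == "density" and self.w is None:
            raise ValueError("density measure requires a density w(t, s)")


def gaussian_measure(a: float) -> MemoryMeasure:
    """Gaussian memory kernel w_t(s) = exp(-a (s - t)^2), a >= 0.

    a = 0 is the flat (uniform-history) limiting kernel. The analytic partial
    derivative dw/dt = -2 a (t - s) w is attached.
    """
    if a < 0:
        raise ValueError("Gaussian width parameter a must be >= 0")
    a = float(a)

    def w(t, s):
        s = np.asarray(s, dtype=float)
        return np.exp(-a * (s - t) ** 2)

    def dw_dt(t, s):
        s = np.asarray(s, dtype=float)
        return -2.0 * a * (t - s) * np.exp(-a * (s - t) ** 2)

    return MemoryMeasure(kind="density", w=w, dw_dt=dw_dt, params={"a": a})


def dirac_measure() -> MemoryMeasure:
    """Memory-free measure mu_t = t * delta(t - s)."""
    return MemoryMeasure(kind="dirac")


def density_measure(w: Callable, dw_dt: Callable | None = None, params: dict | None = None) -> MemoryMeasure:
    """Custom density-kind measure.

    If ``dw_dt`` is omitted it is replaced by a central finite difference
    with step 1e-6 * (1 + t), and the measure is flagged
    ``dw_dt_numeric=True`` so downstream reports can surface the fallback.
    """
    numeric = dw_dt is None
    if numeric:
        def dw_dt(t, s, _w=w):
            h = _FD_STEP(t)
            return (np.asarray(_w(t + h, s), dtype=float) - np.asarray(_w(t - h, s), dtype=float)) / (2 * h)

    return MemoryMeasure(kind="density", w=w, dw_dt=dw_dt, params=params, dw_dt_numeric=numeric)


@dataclass(frozen=True)
class TrophicWeights:
    """Effective trophic potential p_i(t, N, cumN) (> 0) per species.

    ``p`` maps (t, N, cumN) -> length-n positive vector. ``dp_total``, if
    supplied, is the analytic total time derivative d/dt p_i(t, N(t), cumN(t))
    with signature (t, N, cumN, dN_dt) -> vector; otherwise the Dirac-case
    derivative falls back to a central finite difference along the trajectory.
    ``C`` is the optional per-species physiological cap on p_i.
    """

    p: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    dp_total: Callable | None = None
    C: np.ndarray | None = None
    kind: str = "custom"

    def __post_init__(self):
        if self.C is not None:
            C = np.atleast_1d(np.asarray(self.C, dtype=float))
            if np.any(C <= 0):
                raise ValueError("bound C must be strictly positive")
            object.__setattr__(self, "C", C)


def constant_weights(p: Sequence[float] | float, n: int | None = None, C=None) -> TrophicWeights:
    """Species-wise constant potentials p_i (scalar broadcasts over n)."""
    if np.isscalar(p):
        if n is None:
            raise ValueError("n required when p is scalar")
        pvec = np.full(n, float(p))
    else:
        pvec = np.asarray(p, dtype=float)
    if np.any(pvec <= 0):
        raise ValueError("p must be strictly positive")

    def pfun(t, N, cumN, _p=pvec):
        return _p.copy()

    def dp_total(t, N, cumN, dN_dt, _n=pvec.size):
        return np.zeros(_n)

    return TrophicWeights(p=pfun, dp_total=dp_total, C=C, kind="constant")


@dataclass
class TrophicSeries:
    """tau_i and d tau_i/dt sampled on a trajectory grid."""

    t: np.ndarray
    tau: np.ndarray
    dtau_dt: np.ndarray
    measure_kind: str


@dataclass
class WeightBoundReport:
    """Result of checking p_i <= C_i along a trajectory."""

    max_p: np.ndarray
    ok: np.ndarray
    first_violation_time: np.ndarray  # NaN where no violation
    passed: bool


# --------------------------------------------------------------------------
# grid evaluation helpers


class _TrajectoryCache:
    """Grid values of p and f = p * N, plus cubic interpolants for off-grid t.

    ``quad_refine`` inserts that many cubic-interpolated midpoints per grid
    interval into the quadrature node set, shrinking the trapezoid step
    without re-integrating the ODE (the original grid points stay exact
    nodes, so series values on the grid are unchanged in location).
    """

    def __init__(self, traj: Trajectory, weights: TrophicWeights, quad_refine: int = 0):
        self.traj = traj
        G, n = traj.t.size, traj.n
        p = np.empty((G, n))
        for k in range(G):
            p[k] = weights.p(traj.t[k], traj.N[k], traj.cumN[k])
        self.p = p
        self.f = p * traj.N
        self._f_spline = CubicSpline(traj.t, self.f, axis=0)
        self._p_spline = CubicSpline(traj.t, p, axis=0)
        self._N_spline = CubicSpline(traj.t, traj.N, axis=0)
        self.stride = int(quad_refine) + 1
        if quad_refine:
            m = self.stride
            # refined nodes keep the original grid points exactly
            s = np.empty((G - 1) * m + 1)
            for j in range(m):
                s[j:-1:m] = traj.t[:-1] + (traj.t[1:] - traj.t[:-1]) * (j / m)
            s[-1] = traj.t[-1]
            self.s = s
            self.fs = self._f_spline(s)
            self.fs[::m] = self.f  # exact at original grid points
        else:
            self.s = traj.t
            self.fs = self.f

    def f_at(self, t: float) -> np.ndarray:
        return self._f_spline(t)

    def p_at(self, t: float) -> np.ndarray:
        return self._p_spline(t)

    def N_at(self, t: float) -> np.ndarray:
        return self._N_spline(t)


def _density_nodes(traj: Trajectory, cache: _TrajectoryCache, t: float):
    """Trapezoid nodes for [0, t]: quadrature nodes strictly inside plus t."""
    grid = cache.s
    k = int(np.searchsorted(grid, t, side="right"))
    if k > 0 and np.isclose(grid[k - 1], t, rtol=0.0, atol=1e-12 * (1.0 + abs(t))):
        s = grid[:k]
        f = cache.fs[:k]
    else:
        s = np.concatenate([grid[:k], [t]])
        f = np.vstack([cache.fs[:k], cache.f_at(t)])
    return s, f


def _check_span(traj: Trajectory, t: float):
    if not (traj.t[0] <= t <= traj.t[-1]):
        raise ValueError(f"t={t} outside trajectory span [{traj.t[0]}, {traj.t[-1]}]")


def trophic_functional(
    trajectory: Trajectory,
    weights: TrophicWeights,
    measure: MemoryMeasure,
    t: float,
    quad_refine: int = 0,
    _cache: _TrajectoryCache | None = None,
) -> np.ndarray:
    """tau_i(t) under the given measure.

    Density kind: composite trapezoid of p_i N_i w(t, s) over the trajectory
    grid restricted to [0, t], divided by t. The t = 0 value is defined by
    the limit of the prefix average, tau_i(0) = p_i(0) N_i(0) w(0, 0).
    Dirac kind: p_i(t) N_i(t) exactly.
    """
    _check_span(trajectory, t)
    cache = _cache or _TrajectoryCache(trajectory, weights, quad_refine)
    if measure.kind == "dirac":
        return cache.p_at(t) * cache.N_at(t)
    if t == 0.0:
        w00 = float(np.asarray(measure.w(0.0, np.array([0.0])))[0])
        return cache.f[0] * w00
    s, f = _density_nodes(trajectory, cache, t)
    wv = np.asarray(measure.w(t, s), dtype=float)
    return np.trapezoid(f * wv[:, None], s, axis=0) / t


def trophic_derivative(
    trajectory: Trajectory,
    weights: TrophicWeights,
    measure: MemoryMeasure,
    t: float,
    quad_refine: int = 0,
    _cache: _TrajectoryCache | None = None,
) -> np.ndarray:
    """Total derivative d tau_i/dt at time t.

    Density kind evaluates the three-term formula

        -(1/t^2) I0 + (1/t) [ f(t) w(t,t) + I1 ],
        I0 = int f w ds,  I1 = int f dw/dt ds,

    with the same trapezoid nodes as :func:`trophic_functional`. Dirac kind
    applies the chain rule d(p_i N_i)/dt with dN/dt from the GLV right-hand
    side and the analytic ``dp_total`` when available (central finite
    difference along the trajectory otherwise).
    """
    _check_span(trajectory, t)
    cache = _cache or _TrajectoryCache(trajectory, weights, quad_refine)
    if measure.kind == "dirac":
        N = cache.N_at(t)
        cum = np.array([np.interp(t, trajectory.t, trajectory.cumN[:, j]) for j in range(trajectory.n)])
        dN = trajectory.model.rhs(N)
        p = cache.p_at(t)
        if weights.dp_total is not None:
            dp = np.asarray(weights.dp_total(t, N, cum, dN), dtype=float)
        else:
            h = _FD_STEP(t)
            lo = max(trajectory.t[0], t - h)
            hi = min(trajectory.t[-1], t + h)
            dp = (cache.p_at(hi) - cache.p_at(lo)) / (hi - lo)
        return dp * N + p * dN
    if t <= 0.0:
        raise ValueError("density-kind derivative requires t > 0")
    s, f = _density_nodes(trajectory, cache, t)
    wv = np.asarray(measure.w(t, s), dtype=float)
    dwv = np.asarray(measure.dw_dt(t, s), dtype=float)
    I0 = np.trapezoid(f * wv[:, None], s, axis=0)
    I1 = np.trapezoid(f * dwv[:, None], s, axis=0)
    w_tt = float(np.asarray(measure.w(t, np.array([t])))[0])
    f_t = f[-1] if s[-1] == t else cache.f_at(t)
    return -I0 / t**2 + (f_t * w_tt + I1) / t


def trophic_series(
    trajectory: Trajectory,
    weights: TrophicWeights,
    measure: MemoryMeasure,
    quad_refine: int = 0,
) -> TrophicSeries:
    """tau and d tau/dt on the whole trajectory grid.

    For density measures the t = 0 derivative (where the 1/t prefactor is
    singular) is filled by linear extrapolation from the first two interior
    grid points. ``quad_refine`` inserts that many cubic-interpolated
    midpoints per interval into the quadrature node set.
    """
    cache = _TrajectoryCache(trajectory, weights, quad_refine)
    grid = trajectory.t
    G, n = grid.size, trajectory.n
    tau = np.empty((G, n))
    dtau = np.empty((G, n))
    if measure.kind == "dirac":
        tau[:] = cache.f
        for k in range(G):
            dtau[k] = trophic_derivative(trajectory, weights, measure, grid[k], _cache=cache)
        return TrophicSeries(t=grid.copy(), tau=tau, dtau_dt=dtau, measure_kind="dirac")

    w00 = float(np.asarray(measure.w(0.0, np.array([0.0])))[0])
    tau[0] = cache.f[0] * w00
    stride = cache.stride
    for k in range(1, G):
        t = grid[k]
        s = cache.s[: k * stride + 1]
        f = cache.fs[: k * stride + 1]
        wv = np.asarray(measure.w(t, s), dtype=float)
        dwv = np.asarray(measure.dw_dt(t, s), dtype=float)
        I0 = np.trapezoid(f * wv[:, None], s, axis=0)
        I1 = np.trapezoid(f * dwv[:, None], s, axis=0)
        tau[k] = I0 / t
        dtau[k] = -I0 / t**2 + (f[-1] * wv[-1] + I1) / t
    dtau[0] = 2.0 * dtau[1] - dtau[2] if G > 2 else dtau[1]
    return TrophicSeries(t=grid.copy(), tau=tau, dtau_dt=dtau, measure_kind="density")


def check_weight_bound(trajectory: Trajectory, weights: TrophicWeights) -> WeightBoundReport:
    """Verify the physiological cap p_i <= C_i along the whole grid."""
    if weights.C is None:
        raise ValueError("weights carry no bound C to check")
    cache = _TrajectoryCache(trajectory, weights)
    C = np.broadcast_to(weights.C, (trajectory.n,))
    max_p = cache.p.max(axis=0)
    ok = max_p <= C
    first = np.full(trajectory.n, np.nan)
    for i in range(trajectory.n):
        viol = np.nonzero(cache.p[:, i] > C[i])[0]
        if viol.size:
            first[i] = trajectory.t[viol[0]]
    return WeightBoundReport(max_p=max_p, ok=ok, first_violation_time=first, passed=bool(np.all(ok)))


def volterra_trivial_check(
    kernel: Callable[[np.ndarray, np.ndarray], np.ndarray],
    T: float,
    iterations: int,
    grid_size: int = 2048,
) -> np.ndarray:
    """Sup-norms of Picard iterates for phi(t) = int_0^t phi(s) K(t, s) ds.

    Starting from phi_0 = 1 on a uniform grid over [0, T], each iterate is
    the trapezoid-rule image of the previous one; the returned sequence
    ||phi_k||_inf decaying toward zero is the numerical signature that the
    equation admits only the trivial solution. ``kernel`` must be
    numpy-broadcastable over (t, s) arrays; it is never evaluated at t = 0
    (the empty integral pins phi(0) = 0).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    t = np.linspace(0.0, float(T), grid_size)
    h = t[1] - t[0]
    S, Tm = np.meshgrid(t, t)
    mask = S <= Tm
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(mask, np.asarray(kernel(np.maximum(Tm, np.finfo(float).tiny), S), dtype=float), 0.0)
    W = np.tril(np.full((grid_size, grid_size), h))
    W[:, 0] = h / 2.0
    np.fill_diagonal(W, h / 2.0)
    W[0, :] = 0.0
    Aop = K * W
    phi = np.ones(grid_size)
    sups = np.empty(iterations)
    for k in range(iterations):
        phi = Aop @ phi
        sups[k] = np.abs(phi).max()
    return sups
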