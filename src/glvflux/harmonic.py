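"""Exponential trophic potentials, harmonicity constraint, and conic analysis.

The exponential potential

    p_i(t, N, cumN) = exp( -r_i t - sum_j a_ij int_0^t N_j(s) ds )

makes the memory-free trophic functional a conserved quantity along any GLV
trajectory: tau_i(t) = p_i(t) N_i(t) = N_i(0) for all t, hence Y = 0
identically — nontrivial dynamic equilibrium exists in the memory-free
regime.

Requiring each p_i to additionally be harmonic over (t, N_1, ..., N_n)
treated as independent coordinates (vanishing Laplacian, which here reduces
to d^2 p_i/dt^2 = 0) forces the algebraic constraint

    sum_i [ r_i^2 + sum_j a_ij (2 r_i - r_j) N_j
            + sum_j sum_k a_ij (a_ik - a_jk) N_j N_k ] = 0,

a quadratic variety in phase space on which the net energy flow vanishes.
For n = 2 this is a conic whose discriminant turns out to be a perfect
square, D = [a12 (a11 - a21) - a21 (a22 - a12)]^2 >= 0: the constraint curve
is degenerate/parabolic or hyperbolic, never elliptic. (Closed elliptic
orbits in the phase portrait arise from the GLV dynamics themselves, not
from this conic.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glv import GLVModel, Trajectory
from .memory import TrophicWeights

__all__ = [
    "HarmonicityConstraint",
    "ConicCoefficients",
    "harmonic_weights",
    "laplacian_residual",
    "constraint_coefficients",
    "constraint_evaluate",
    "conic_coefficients_2d",
    "constraint_curve_points",
]


@dataclass(frozen=True)
class HarmonicityConstraint:
    """Coefficients of the quadratic harmonicity identity.

    constant = sum_i r_i^2 (>= 0); linear[j] = sum_i a_ij (2 r_i - r_j);
    quadratic is the symmetrized form of Q_raw[j, k] = sum_i a_ij (a_ik - a_jk)
    (the raw matrix is kept for oracle comparisons — N' Q N is insensitive to
    the symmetrization).
    """

    n: int
    constant: float
    linear: np.ndarray
    quadratic: np.ndarray
    quadratic_raw: np.ndarray


@dataclass(frozen=True)
class ConicCoefficients:
    """The n = 2 conic form of the harmonicity constraint.

    c1..c6 are the normalized coefficients with normalization K (chosen as
    r1^2 + r2^2 when positive, so c6 = -1; fallback K = 1). D is the conic
    discriminant (cross^2 - 4 * q11 * q22) of the *unnormalized* quadratic
    part, so the classification is K-independent.
    """

    c: tuple[float, float, float, float, float, float]
    K: float
    D: float
    conic_class: str


def harmonic_weights(model: GLVModel) -> TrophicWeights:
    """Exponential potentials p_i = exp(-r_i t - (A cumN)_i).

    Strictly positive by construction; p_i(0) = 1. The analytic total
    derivative d p_i/dt = -(r_i + (A N)_i) p_i is attached, so the Dirac-case
    chain rule cancels the GLV growth exactly and tau_i stays at N_i(0).
    """
    r, A = model.r, model.A

    def p(t, N, cumN):
        return np.exp(-r * t - A @ np.asarray(cumN, dtype=float))

    def dp_total(t, N, cumN, dN_dt):
        return -(r + A @ np.asarray(N, dtype=float)) * p(t, N, cumN)

    return TrophicWeights(p=p, dp_total=dp_total, kind="harmonic")


def laplacian_residual(model: GLVModel, trajectory: Trajectory, t: float) -> np.ndarray:
    """Laplacian of the exponential potential at a grid time.

    Delta p_i = [ (r_i + (A N)_i)^2 - (A Ndot)_i ] p_i with Ndot from the GLV
    right-hand side; a zero residual means p_i is (numerically) harmonic at
    that state.
    """
    k = int(np.argmin(np.abs(trajectory.t - t)))
    if not np.isclose(trajectory.t[k], t, rtol=0.0, atol=1e-9 * (1.0 + abs(t))):
        raise ValueError(f"t={t} is not a grid time of the trajectory")
    N = trajectory.N[k]
    cum = trajectory.cumN[k]
    p = np.exp(-model.r * trajectory.t[k] - model.A @ cum)
    g = model.growth_rates(N)
    Ndot = N * g
    return (g**2 - model.A @ Ndot) * p


def constraint_coefficients(model: GLVModel) -> HarmonicityConstraint:
    """Constant/linear/quadratic coefficients of the harmonicity identity."""
    r, A, n = model.r, model.A, model.n
    constant = float(np.sum(r**2))
    # L_j = sum_i a_ij (2 r_i - r_j)
    linear = np.array([float(np.sum(A[:, j] * (2.0 * r - r[j]))) for j in range(n)])
    # Q_raw[j, k] = sum_i a_ij (a_ik - a_jk)
    Q_raw = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            Q_raw[j, k] = np.sum(A[:, j] * (A[:, k] - A[j, k]))
    Q_sym = 0.5 * (Q_raw + Q_raw.T)
    return HarmonicityConstraint(n=n, constant=constant, linear=linear,
                                 quadratic=Q_sym, quadratic_raw=Q_raw)


def constraint_evaluate(constraint: HarmonicityConstraint, N) -> float:
    """gamma0 + L . N + N' Q N at a population state."""
    N = np.asarray(N, dtype=float)
    if N.shape != (constraint.n,):
        raise ValueError(f"state must have length {constraint.n}")
    return float(constraint.constant + constraint.linear @ N + N @ constraint.quadratic @ N)


def conic_coefficients_2d(model: GLVModel, tol: float | None = None) -> ConicCoefficients:
    """Conic form and classification of the n = 2 harmonicity constraint.

    The printed normalized coefficients are

        c1 = q11/K   c2 = q12/K   c3 = q22/K
        c4 = L2/K    c5 = L1/K    c6 = -(r1^2 + r2^2)/K

    with q11 = a21 (a21 - a11), q22 = a12 (a12 - a22),
    q12 = a12 (a11 - a21) + a21 (a22 - a12), L as in
    :func:`constraint_coefficients`, and K = r1^2 + r2^2 when positive
    (making c6 = -1), else K = 1. Classification uses the K-independent
    discriminant D = q12^2 - 4 q11 q22 of the raw quadratic part, with a
    scale-aware tolerance.
    """
    if model.n != 2:
        raise ValueError("conic analysis requires a two-species model")
    r, A = model.r, model.A
    a11, a12 = A[0]
    a21, a22 = A[1]
    r1, r2 = r
    q11 = a21 * (a21 - a11)
    q22 = a12 * (a12 - a22)
    q12 = a12 * (a11 - a21) + a21 * (a22 - a12)
    l1 = a11 * r1 + a21 * (2.0 * r2 - r1)
    l2 = a12 * (2.0 * r1 - r2) + a22 * r2
    gamma0 = r1**2 + r2**2
    K = gamma0 if gamma0 > 0 else 1.0
    c = (q11 / K, q12 / K, q22 / K, l2 / K, l1 / K, -gamma0 / K)
    D = q12**2 - 4.0 * q11 * q22
    if tol is None:
        tol = 1e-12 * (1.0 + max(abs(q11), abs(q12), abs(q22)) ** 2)
    if D > tol:
        klass = "hyperbolic"
    elif D < -tol:
        klass = "elliptic"
    else:
        klass = "degenerate/parabolic"
    return ConicCoefficients(c=c, K=float(K), D=float(D), conic_class=klass)


def constraint_curve_points(
    constraint: HarmonicityConstraint,
    window: tuple[float, float, float, float],
    grid: int = 400,
) -> np.ndarray:
    """Sample the zero set of the n = 2 constraint by dense grid signing.

    ``window`` is (N1_min, N1_max, N2_min, N2_max). Returns an array of
    (N1, N2) midpoints of grid edges across which the constraint changes
    sign — a plot-ready sampling of the curve, no contouring library needed.
    """
    if constraint.n != 2:
        raise ValueError("curve sampling requires a two-species constraint")
    x = np.linspace(window[0], window[1], grid)
    y = np.linspace(window[2], window[3], grid)
    X, Y = np.meshgrid(x, y, indexing="ij")
    V = (constraint.constant
         + constraint.linear[0] * X + constraint.linear[1] * Y
         + constraint.quadratic[0, 0] * X**2
         + 2.0 * constraint.quadratic[0, 1] * X * Y
         + constraint.quadratic[1, 1] * Y**2)
    pts = []
    sx = np.signbit(V[:-1, :]) != np.signbit(V[1:, :])
    ii, jj = np.nonzero(sx)
    pts.append(np.column_stack([(x[ii] + x[ii + 1]) / 2.0, y[jj]]))
    sy = np.signbit(V[:, :-1]) != np.signbit(V[:, 1:])
    ii, jj = np.nonzero(sy)
    pts.append(np.column_stack([x[ii], (y[jj] + y[jj + 1]) / 2.0]))
    return np.vstack(pts) if pts else np.empty((0, 2))
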