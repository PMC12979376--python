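"""Generalized Lotka-Volterra systems: definition, integration, local analysis.

The model is the n-species system

    dN_i/dt = N_i ( r_i + sum_j a_ij N_j ),    N(0) = N0 > 0,

with intrinsic rate vector ``r`` and interaction matrix ``A``. Solutions
starting in the open positive orthant stay there for as long as they exist;
integration is therefore performed in log-abundance coordinates

    d log N_i / dt = r_i + (A N)_i,

which enforces positivity exactly. The running integrals
``cumN_j(t) = int_0^t N_j(s) ds`` (needed by the history-weighted trophic
functionals) are carried as additional ODE states inside the same solve, so
that linear conservation laws of the pair (log N, cumN) are preserved to
roundoff by the Runge-Kutta stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

__all__ = [
    "GLVModel",
    "Trajectory",
    "EquilibriumReport",
    "BlowUpError",
    "integrate_glv",
    "coexistence_equilibrium",
    "stability_at",
    "cumulative_abundances",
]

# Log-abundance ceiling used for blow-up detection: exp(700) is near the
# double-precision overflow threshold.
LOG_ABUNDANCE_CEILING = 700.0

# Relative tolerance below which an eigenvalue real part counts as zero when
# classifying an equilibrium.
EIGENVALUE_ZERO_RTOL = 1e-9


class BlowUpError(RuntimeError):
    """Finite-time blow-up detected before the requested horizon.

    Attributes
    ----------
    t_last : float
        Last time at which the solution was still valid.
    """

    def __init__(self, message: str, t_last: float):
        super().__init__(message)
        self.t_last = float(t_last)


@dataclass(frozen=True)
class GLVModel:
    """An n-species generalized Lotka-Volterra system (r, A).

    Parameters
    ----------
    r : array_like, shape (n,)
        Intrinsic growth/decay rates (per unit time).
    A : array_like, shape (n, n)
        Interaction matrix (per abundance per unit time).
    labels : sequence of str, optional
        Species names.
    """

    r: np.ndarray
    A: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if r.ndim != 1:
            raise ValueError("r must be a vector")
        n = r.shape[0]
        if n < 1:
            raise ValueError("at least one species required")
        if A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {A.shape}")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(A))):
            raise ValueError("r and A must be finite")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length must match species count")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "A", A)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def rhs(self, N: np.ndarray) -> np.ndarray:
        """GLV right-hand side dN/dt at state N."""
        N = np.asarray(N, dtype=float)
        return N * (self.r + self.A @ N)

    def growth_rates(self, N: np.ndarray) -> np.ndarray:
        """Per-capita growth rates r + A N at state N."""
        return self.r + self.A @ np.asarray(N, dtype=float)

    # ---- JSON I/O -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"n": self.n, "r": self.r.tolist(), "A": self.A.tolist()}
        if self.labels is not None:
            d["labels"] = list(self.labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GLVModel":
        model = cls(r=d["r"], A=d["A"], labels=d.get("labels"))
        if "n" in d and int(d["n"]) != model.n:
            raise ValueError("declared n inconsistent with r/A")
        return model

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GLVModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Trajectory:
    """A GLV solution sampled on an output grid.

    ``cumN[k, j]`` is the running integral of species j's abundance over
    [0, t_k], carried as an ODE state alongside N (solver-accurate, not a
    posteriori quadrature; see :func:`cumulative_abundances` for the
    trapezoid variant on the same grid).
    """

    model: GLVModel
    t: np.ndarray
    N: np.ndarray
    cumN: np.ndarray
    N0: np.ndarray = field(default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.cumN = np.asarray(self.cumN, dtype=float)
        if self.N0 is None:
            self.N0 = self.N[0].copy()
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.N.shape != (self.t.size, self.model.n):
            raise ValueError("N shape inconsistent with grid/model")

    @property
    def n(self) -> int:
        return self.model.n

    def state_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (N, cumN) at time t within the span."""
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside trajectory span")
        N = np.array([np.interp(t, self.t, self.N[:, j]) for j in range(self.n)])
        c = np.array([np.interp(t, self.t, self.cumN[:, j]) for j in range(self.n)])
        return N, c

    def to_csv(self, path) -> None:
        """Write `t,N_1..N_n,cum_1..cum_n` with repr round-trip precision."""
        n = self.n
        header = ["t"] + [f"N_{j + 1}" for j in range(n)] + [f"cum_{j + 1}" for j in range(n)]
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for k in range(self.t.size):
                row = [repr(float(self.t[k]))]
                row += [repr(float(v)) for v in self.N[k]]
                row += [repr(float(v)) for v in self.cumN[k]]
                fh.write(",".join(row) + "\n")


@dataclass
class EquilibriumReport:
    """Local linear analysis of a GLV state."""

    point: np.ndarray | None
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    classification: str


def integrate_glv(
    model: GLVModel,
    N0: Sequence[float],
    t_end: float,
    dt_out: float = 0.01,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    method: str = "DOP853",
) -> Trajectory:
    """Integrate the GLV system in log-abundance coordinates.

    Parameters
    ----------
    N0 : strictly positive initial abundances.
    t_end : horizon (> 0).
    dt_out : output grid step; the grid is the uniform linspace closest to it.
    rtol, atol : solver tolerances applied to (log N, cumN).

    Returns
    -------
    Trajectory on the grid {0, ~dt_out, ..., t_end}.

    Raises
    ------
    ValueError
        For non-positive N0 or t_end.
    BlowUpError
        If a finite-time blow-up is detected before t_end (log-abundance
        exceeding ~700 or solver step collapse); carries the last valid time.
    """
    N0 = np.asarray(N0, dtype=float)
    if N0.shape != (model.n,):
        raise ValueError("N0 length must match species count")
    if np.any(N0 <= 0) or not np.all(np.isfinite(N0)):
        raise ValueError("N0 must be strictly positive and finite")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    n = model.n
    r, A = model.r, model.A

    def rhs(t, y):
        N = np.exp(y[:n])
        dx = r + A @ N
        return np.concatenate([dx, N])

    def blow_up(t, y):
        return np.max(y[:n]) - LOG_ABUNDANCE_CEILING

    blow_up.terminal = True
    blow_up.direction = 1

    npts = max(2, int(round(t_end / dt_out)) + 1)
    grid = np.linspace(0.0, t_end, npts)
    y0 = np.concatenate([np.log(N0), np.zeros(n)])
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        events=blow_up,
        dense_output=False,
    )
    if sol.status == 1:  # terminated by the blow-up event
        t_last = sol.t_events[0][0] if sol.t_events[0].size else (sol.t[-1] if sol.t.size else 0.0)
        raise BlowUpError(
            f"finite-time blow-up detected near t={t_last:.6g} (before t_end={t_end})",
            t_last,
        )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else 0.0
        raise BlowUpError(
            f"integrator failed near t={t_last:.6g}: {sol.message}", t_last
        )
    N = np.exp(sol.y[:n].T)
    cumN = sol.y[n:].T.copy()
    cumN[0] = 0.0
    return Trajectory(model=model, t=sol.t.copy(), N=N, cumN=cumN, N0=N0.copy())


def coexistence_equilibrium(model: GLVModel) -> np.ndarray | None:
    """Interior equilibrium N* solving r + A N* = 0, or None.

    Returns None when A is singular, the solution is non-finite, or any
    coordinate is not strictly positive (absence is a value, not an error).
    """
    try:
        Nstar = np.linalg.solve(model.A, -model.r)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(Nstar)) or np.any(Nstar <= 0):
        return None
    return Nstar


def _classify_eigenvalues(eig: np.ndarray) -> str:
    scale = np.max(np.abs(eig)) if eig.size else 0.0
    if scale == 0.0:
        return "degenerate"
    tol = EIGENVALUE_ZERO_RTOL * scale
    re, im = eig.real, eig.imag
    zero = np.abs(re) <= tol
    if np.all(zero):
        if np.any(np.abs(im) > tol):
            return "center (linear)"
        return "degenerate"
    if np.any(zero):
        return "degenerate"
    oscillatory = np.any(np.abs(im) > tol)
    if np.all(re < 0):
        return "stable focus" if oscillatory else "stable node"
    if np.all(re > 0):
        return "unstable focus" if oscillatory else "unstable node"
    return "saddle"


def stability_at(model: GLVModel, point: Sequence[float]) -> EquilibriumReport:
    """Jacobian analysis of the GLV vector field at a strictly positive state.

    J = diag(point) A + diag(r + A point); at an interior equilibrium the
    second term vanishes. Eigenvalue real parts smaller than
    ``EIGENVALUE_ZERO_RTOL`` times the spectral radius count as zero, so a
    purely imaginary pair classifies as "center (linear)".
    """
    point = np.asarray(point, dtype=float)
    if np.any(point <= 0):
        raise ValueError("point must be strictly positive")
    J = np.diag(point) @ model.A + np.diag(model.growth_rates(point))
    eig = np.linalg.eigvals(J)
    return EquilibriumReport(
        point=point,
        jacobian=J,
        eigenvalues=eig,
        classification=_classify_eigenvalues(eig),
    )


def cumulative_abundances(trajectory: Trajectory) -> np.ndarray:
    """Trapezoid-rule running integrals of N on the output grid.

    First row is zero; columns are nondecreasing for positive trajectories.
    This is the declared quadrature rule shared by the trophic/flux
    functionals; ``Trajectory.cumN`` is its solver-accurate counterpart and
    the two agree to O(dt_out^2).
    """
    return cumulative_trapezoid(trajectory.N, trajectory.t, axis=0, initial=0.0)
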