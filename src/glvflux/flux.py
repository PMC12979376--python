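"""Biomass budget: total biomass M, abiotic reservoir R, and flux Y.

The prescribed C^1 total-biomass function M(t) bounds the trophically
allocated biomass: the standing assumption is M(t) >= sum_i tau_i(t). The
abiotic reservoir is the unallocated remainder

    R(t) = M(t) - sum_i tau_i(t),

and the net energetic exchange between the neighborhood and the reservoir is
the flux functional

    Y(t) = d/dt [ M(t) - R(t) ] = sum_i d tau_i/dt,

whose sign separates accumulation (Y > 0), depletion (Y < 0) and dynamic
equilibrium (Y = 0). Both routes to Y are computed and cross-checked: the
sum of the trophic derivatives (formula route, ``Y_sum``) and the finite
difference of the M - R series (budget route, ``Y_budget``); their agreement
is the numerical content of the continuity equation M' = sum_i tau_i' + R'.

Units: biomass and "energy" flow are kept on one (mass, mass/time) scale
throughout; the framework deliberately does not separate caloric from mass
flow.

The sign triple (Y, M', R') at each time is mapped onto the scenario
taxonomy a..h (plus "null" for the fully steady state and "mixed" for sign
triples inconsistent with Y = M' - R'):

    Y > 0:  (M'>0, R'>=0) -> a   (M'>0, R'<0) -> b   (M'<=0, R'<0) -> c
    Y < 0:  (M'>=0, R'>0) -> d   (M'<0, R'>0) -> e   (M'<0, R'<0) -> f
    Y = 0:  (M'>0, R'>0) -> g    (M'<0, R'<0) -> h   (M'=0, R'=0) -> null
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .glv import Trajectory
from .memory import (
    MemoryMeasure,
    TrophicSeries,
    TrophicWeights,
    trophic_series,
)

__all__ = [
    "BiomassBudget",
    "FluxSeries",
    "MemoryEquilibriumReport",
    "constant_budget",
    "linear_budget",
    "sinusoidal_budget",
    "expression_budget",
    "reservoir_series",
    "flux_series",
    "classify_scenarios",
    "memory_equilibrium_diagnostic",
]

#: Default relative deadband for sign classification: |x| <= eps -> 0 with
#: eps = DEADBAND_RTOL * flux scale over the window (scale-free; see
#: classify_scenarios for the scale definition).
DEADBAND_RTOL = 1e-9


@dataclass(frozen=True)
class BiomassBudget:
    """Prescribed total biomass M(t) and its derivative.

    ``dM_numeric`` flags a finite-difference fallback derivative (step
    1e-6 * (1 + t)); prefer supplying the analytic dM/dt.
    """

    M: Callable[[float], float]
    dM_dt: Callable[[float], float]
    dM_numeric: bool = False
    spec: dict | None = None


def _fd_derivative(M):
    def dM(t, _M=M):
        h = 1e-6 * (1.0 + abs(t))
        return (_M(t + h) - _M(t - h)) / (2.0 * h)

    return dM


def constant_budget(value: float) -> BiomassBudget:
    if value <= 0:
        raise ValueError("total biomass must be positive")
    v = float(value)
    return BiomassBudget(
        M=lambda t: v + 0.0 * t,
        dM_dt=lambda t: 0.0 * t,
        spec={"kind": "constant", "value": v},
    )


def linear_budget(m0: float, slope: float) -> BiomassBudget:
    m0, slope = float(m0), float(slope)
    return BiomassBudget(
        M=lambda t: m0 + slope * t,
        dM_dt=lambda t: slope + 0.0 * t,
        spec={"kind": "linear", "m0": m0, "slope": slope},
    )


def sinusoidal_budget(m0: float, amplitude: float, omega: float, phase: float = 0.0) -> BiomassBudget:
    m0, amplitude, omega, phase = map(float, (m0, amplitude, omega, phase))
    return BiomassBudget(
        M=lambda t: m0 + amplitude * np.sin(omega * t + phase),
        dM_dt=lambda t: amplitude * omega * np.cos(omega * t + phase),
        spec={"kind": "sinusoidal", "m0": m0, "amplitude": amplitude, "omega": omega, "phase": phase},
    )


_EXPR_NAMESPACE = {
    "sin": np.sin, "cos": np.cos, "tan": np.tan, "exp": np.exp, "log": np.log,
    "sqrt": np.sqrt, "abs": np.abs, "pi": np.pi, "e": np.e, "tanh": np.tanh,
}


def expression_budget(text: str) -> BiomassBudget:
    """Budget from a numpy expression in the single variable ``t``.

    Dialect: python arithmetic plus sin, cos, tan, tanh, exp, log, sqrt, abs,
    pi, e. The derivative is a central finite difference (flagged
    ``dM_numeric``).
    """
    code = compile(text, "<budget>", "eval")

    def M(t, _code=code):
        return float(eval(_code, {"__builtins__": {}}, {**_EXPR_NAMESPACE, "t": t}))

    return BiomassBudget(M=M, dM_dt=_fd_derivative(M), dM_numeric=True,
                         spec={"kind": "expression", "text": text})


@dataclass
class FluxSeries:
    """Grid series of the full biomass budget.

    ``Y_sum`` is sum_i d tau_i/dt (formula route); ``Y_budget`` is the
    central finite difference of the M - R = sum tau series (budget route);
    ``y_discrepancy`` is their max absolute gap. ``budget_violations`` marks
    grid points where R < 0, i.e. where M < sum tau breaks the standing
    budget assumption.
    """

    t: np.ndarray
    tau: np.ndarray
    dtau_dt: np.ndarray
    R: np.ndarray
    M: np.ndarray
    Mp: np.ndarray
    Rp: np.ndarray
    Y_sum: np.ndarray
    Y_budget: np.ndarray
    y_discrepancy: float
    measure_kind: str
    budget_violations: np.ndarray
    sup_abs_N: float
    scenarios: np.ndarray | None = None
    dM_numeric: bool = False

    @property
    def Y(self) -> np.ndarray:
        """The flux series (formula route)."""
        return self.Y_sum

    def to_csv(self, path) -> None:
        """Write `t,tau_1..tau_n,R,M,dM,dR,Y_sum,Y_budget,scenario`."""
        n = self.tau.shape[1]
        scen = self.scenarios if self.scenarios is not None else classify_scenarios(self)
        header = (["t"] + [f"tau_{j + 1}" for j in range(n)]
                  + ["R", "M", "dM", "dR", "Y_sum", "Y_budget", "scenario"])
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for k in range(self.t.size):
                row = [repr(float(self.t[k]))]
                row += [repr(float(v)) for v in self.tau[k]]
                row += [repr(float(v)) for v in
                        (self.R[k], self.M[k], self.Mp[k], self.Rp[k], self.Y_sum[k], self.Y_budget[k])]
                row.append(str(scen[k]))
                fh.write(",".join(row) + "\n")


def reservoir_series(budget: BiomassBudget, tau: TrophicSeries) -> np.ndarray:
    """R(t) = M(t) - sum_i tau_i(t) on the series grid.

    Negative values (budget violations) are returned as-is but trigger a
    warning; downstream ``FluxSeries.budget_violations`` carries the flags.
    """
    M = np.array([float(budget.M(tk)) for tk in tau.t])
    R = M - tau.tau.sum(axis=1)
    if np.any(R < 0):
        warnings.warn("budget violation: M(t) < sum tau_i(t) at some grid points", stacklevel=2)
    return R


def flux_series(
    trajectory: Trajectory,
    weights: TrophicWeights,
    measure: MemoryMeasure,
    budget: BiomassBudget,
    classify: bool = True,
    eps: float | None = None,
    quad_refine: int = 0,
) -> FluxSeries:
    """Full budget series: tau, d tau/dt, R, M', R', Y by both routes.

    R' is obtained from the continuity identity R' = M' - sum_i d tau_i/dt.
    ``Y_budget`` differentiates the sum-tau series by central finite
    differences (one-sided at the ends) as an independent cross-check.
    """
    series = trophic_series(trajectory, weights, measure, quad_refine=quad_refine)
    t = series.t
    M = np.array([float(budget.M(tk)) for tk in t])
    Mp = np.array([float(budget.dM_dt(tk)) for tk in t])
    sum_tau = series.tau.sum(axis=1)
    R = M - sum_tau
    Y_sum = series.dtau_dt.sum(axis=1)
    Rp = Mp - Y_sum
    Y_budget = np.gradient(sum_tau, t)
    interior = slice(1, -1) if t.size > 2 else slice(None)
    disc = float(np.max(np.abs(Y_sum[interior] - Y_budget[interior])))
    fs = FluxSeries(
        t=t, tau=series.tau, dtau_dt=series.dtau_dt, R=R, M=M, Mp=Mp, Rp=Rp,
        Y_sum=Y_sum, Y_budget=Y_budget, y_discrepancy=disc,
        measure_kind=series.measure_kind,
        budget_violations=R < 0,
        sup_abs_N=float(np.max(np.abs(trajectory.N))),
        dM_numeric=budget.dM_numeric,
    )
    if np.any(fs.budget_violations):
        warnings.warn("budget violation: M(t) < sum tau_i(t) at some grid points", stacklevel=2)
    if classify:
        fs.scenarios = classify_scenarios(fs, eps=eps)
    return fs


_SCENARIOS_POS = {(1, 1): "a", (1, 0): "a", (1, -1): "b", (0, -1): "c", (-1, -1): "c"}
_SCENARIOS_NEG = {(1, 1): "d", (0, 1): "d", (-1, 1): "e", (-1, -1): "f"}
_SCENARIOS_ZERO = {(1, 1): "g", (-1, -1): "h", (0, 0): "null"}


def classify_scenarios(flux: FluxSeries, eps: float | None = None) -> np.ndarray:
    """Label each grid point with its energy-flow scenario.

    Signs are taken with a deadband (|x| <= eps counts as zero); the default
    eps is ``DEADBAND_RTOL`` times the flux scale of the window, taken as the
    larger of max |Y| and the mean trophic turnover max|sum tau| / span (the
    floor keeps roundoff-level Y in a conserved regime from being classified
    as signal). Sign triples that are arithmetically impossible under
    Y = M' - R' outside the deadband map to "mixed".
    """
    if eps is None:
        span = flux.t[-1] - flux.t[0] if flux.t.size > 1 else 1.0
        turnover = float(np.max(np.abs(flux.tau.sum(axis=1)))) / max(span, 1e-300)
        eps = DEADBAND_RTOL * max(float(np.max(np.abs(flux.Y_sum))), turnover) if flux.t.size else 0.0
    if eps < 0:
        raise ValueError("deadband eps must be >= 0")

    def sgn(x):
        return np.where(np.abs(x) <= eps, 0, np.sign(x)).astype(int)

    sy, sm, sr = sgn(flux.Y_sum), sgn(flux.Mp), sgn(flux.Rp)
    out = np.empty(flux.t.size, dtype=object)
    for k in range(flux.t.size):
        if sy[k] > 0:
            out[k] = _SCENARIOS_POS.get((sm[k], sr[k]), "mixed")
        elif sy[k] < 0:
            out[k] = _SCENARIOS_NEG.get((sm[k], sr[k]), "mixed")
        else:
            out[k] = _SCENARIOS_ZERO.get((sm[k], sr[k]), "mixed")
    return out


@dataclass
class MemoryEquilibriumReport:
    """Numerical check of the memory-regime dichotomy.

    For absolutely continuous (density) measures, the flux Y vanishes
    identically only for the trivial (extinct) trajectory. The report states
    sup|Y| and sup|N| over the window and the verdict:
    "trivial (extinct), Y ~ 0" or "nontrivial, Y not identically 0".
    """

    sup_Y: float
    sup_N: float
    population_tol: float
    flux_floor: float | None
    consistent: bool
    verdict: str


def memory_equilibrium_diagnostic(
    flux: FluxSeries,
    population_tol: float = 1e-12,
    flux_floor: float | None = None,
) -> MemoryEquilibriumReport:
    """Assert the density-measure dichotomy: Y == 0 iff N == 0.

    ``flux_floor`` is the fixture-specific positive floor that sup|Y| must
    exceed for a nontrivial trajectory; when omitted only the trivial branch
    is checked quantitatively. Calling this with a Dirac-measure flux is a
    misuse (the dichotomy holds only for absolutely continuous measures).
    """
    if flux.measure_kind != "density":
        raise ValueError("diagnostic applies only to density-kind (absolutely continuous) measures")
    sup_Y = float(np.max(np.abs(flux.Y_sum)))
    sup_N = flux.sup_abs_N
    if sup_N <= population_tol:
        consistent = sup_Y <= max(1e-9 * float(np.max(np.abs(flux.M))), 1e-30)
        verdict = "trivial (extinct), Y ~ 0" if consistent else "trivial N but Y not ~ 0 (inconsistent)"
    else:
        consistent = sup_Y > (flux_floor if flux_floor is not None else 0.0)
        verdict = ("nontrivial, Y not identically 0" if consistent
                   else "nontrivial N but sup|Y| below floor (inconsistent)")
    return MemoryEquilibriumReport(
        sup_Y=sup_Y, sup_N=sup_N, population_tol=population_tol,
        flux_floor=flux_floor, consistent=consistent, verdict=verdict,
    )
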