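"""Planar phase-portrait tooling: period detection, orbit classification,
cycle averages.

For the classical two-species predator-prey system the coexistence
equilibrium is a center and every interior orbit is a closed curve around
it; the time average of each population over one full cycle equals its
equilibrium value. The period is detected with a Poincare section: the
vertical line N1 = N1* through the equilibrium, crossed in a fixed
direction on the N2 > N2* branch, with sub-grid crossing times from linear
interpolation. An orbit is accepted as closed when the state-space gap
between successive returns is below 1% of the orbit diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glv import Trajectory

__all__ = [
    "OrbitReport",
    "detect_period",
    "cycle_average",
    "classify_orbit",
]

#: Return-gap acceptance threshold for closed orbits, as a fraction of the
#: orbit diameter.
RETURN_GAP_RTOL = 0.01

#: Escape detector: any abundance exceeding this multiple of its initial
#: value, or dropping below the positivity floor, marks an open orbit.
ESCAPE_GROWTH_FACTOR = 1e6
POSITIVITY_FLOOR = 1e-12

#: Orbit diameter (relative to the initial state) below which the
#: trajectory counts as sitting at a fixed point.
FIXED_POINT_RTOL = 1e-8


@dataclass
class OrbitReport:
    """Classification of a planar orbit."""

    classification: str  # "closed" | "open/escaping" | "fixed-point"
    period: float | None = None
    cycle_average: np.ndarray | None = None
    return_gap: float | None = None


def _section_crossings(traj: Trajectory, anchor: np.ndarray):
    """Interpolated crossing times/states of the line N1 = anchor1, N2 > anchor2.

    Crossings are grouped by direction (sign of dN1 across the section); the
    dominant same-direction family is returned.
    """
    g = traj.N[:, 0] - anchor[0]
    idx = np.nonzero(g[:-1] * g[1:] < 0)[0]
    crossings = {1: [], -1: []}
    for i in idx:
        frac = g[i] / (g[i] - g[i + 1])
        tc = traj.t[i] + frac * (traj.t[i + 1] - traj.t[i])
        N2c = traj.N[i, 1] + frac * (traj.N[i + 1, 1] - traj.N[i, 1])
        if N2c <= anchor[1]:
            continue
        direction = 1 if g[i + 1] > g[i] else -1
        crossings[direction].append((tc, N2c))
    best = max(crossings.values(), key=len)
    return best


def detect_period(trajectory: Trajectory, anchor) -> float | None:
    """Orbit period from successive same-direction Poincare-section returns.

    Returns None when fewer than two same-direction crossings exist or the
    return gap in state space exceeds ``RETURN_GAP_RTOL`` of the orbit
    diameter (open or non-returning orbit).
    """
    if trajectory.n != 2:
        raise ValueError("period detection requires a two-species trajectory")
    anchor = np.asarray(anchor, dtype=float)
    crossings = _section_crossings(trajectory, anchor)
    if len(crossings) < 2:
        return None
    (t0, n2a), (t1, n2b) = crossings[0], crossings[1]
    diam = float(np.linalg.norm(trajectory.N.max(axis=0) - trajectory.N.min(axis=0)))
    gap = abs(n2b - n2a)  # both returns sit on N1 = anchor1 exactly
    if diam == 0.0 or gap > RETURN_GAP_RTOL * diam:
        return None
    return float(t1 - t0)


def cycle_average(trajectory: Trajectory, period: float) -> np.ndarray:
    """Trapezoid time-average of N over exactly one period from t = t0.

    For a closed orbit the average over any window of one full period is the
    same, so the window [t0, t0 + T] at the start of the trajectory is used;
    the right endpoint is linearly interpolated between grid points.
    """
    if period is None or period <= 0:
        raise ValueError("a positive detected period is required")
    t0 = trajectory.t[0]
    t_end = t0 + period
    if t_end > trajectory.t[-1] + 1e-12 * (1.0 + abs(t_end)):
        raise ValueError("trajectory span shorter than one period")
    k = int(np.searchsorted(trajectory.t, t_end, side="right"))
    ts = trajectory.t[:k]
    Ns = trajectory.N[:k]
    if ts[-1] < t_end:
        N_end = np.array([np.interp(t_end, trajectory.t, trajectory.N[:, j])
                          for j in range(trajectory.n)])
        ts = np.concatenate([ts, [t_end]])
        Ns = np.vstack([Ns, N_end])
    return np.trapezoid(Ns, ts, axis=0) / period


def classify_orbit(trajectory: Trajectory, equilibrium) -> OrbitReport:
    """Combined closed / open-escaping / fixed-point classification."""
    if trajectory.n != 2:
        raise ValueError("orbit classification requires a two-species trajectory")
    equilibrium = np.asarray(equilibrium, dtype=float)
    N0 = trajectory.N0
    spread = trajectory.N.max(axis=0) - trajectory.N.min(axis=0)
    if np.all(spread <= FIXED_POINT_RTOL * (np.abs(N0) + 1e-300)):
        return OrbitReport(classification="fixed-point")
    if np.any(trajectory.N > ESCAPE_GROWTH_FACTOR * N0) or np.any(trajectory.N < POSITIVITY_FLOOR):
        return OrbitReport(classification="open/escaping")
    crossings = _section_crossings(trajectory, equilibrium)
    if len(crossings) < 2:
        return OrbitReport(classification="open/escaping")
    (t0, n2a), (t1, n2b) = crossings[0], crossings[1]
    diam = float(np.linalg.norm(spread))
    gap = abs(n2b - n2a)
    if gap > RETURN_GAP_RTOL * diam:
        return OrbitReport(classification="open/escaping", return_gap=gap)
    period = float(t1 - t0)
    # average over one detected period starting at the first return
    sub = _window(trajectory, t0, t0 + period)
    avg = cycle_average(sub, period)
    return OrbitReport(classification="closed", period=period,
                       cycle_average=avg, return_gap=gap)


def _window(traj: Trajectory, t0: float, t1: float) -> Trajectory:
    """Sub-trajectory restricted to [t0, t1] with interpolated endpoints."""
    mask = (traj.t > t0) & (traj.t < t1)
    ts = traj.t[mask]
    Ns = traj.N[mask]
    cs = traj.cumN[mask]

    def interp_row(t):
        N = np.array([np.interp(t, traj.t, traj.N[:, j]) for j in range(traj.n)])
        c = np.array([np.interp(t, traj.t, traj.cumN[:, j]) for j in range(traj.n)])
        return N, c

    N_a, c_a = interp_row(t0)
    N_b, c_b = interp_row(t1)
    ts = np.concatenate([[t0], ts, [t1]])
    Ns = np.vstack([N_a, Ns, N_b])
    cs = np.vstack([c_a, cs, c_b])
    return Trajectory(model=traj.model, t=ts, N=Ns, cumN=cs, N0=N_a)
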