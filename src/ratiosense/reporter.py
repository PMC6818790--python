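"""Maturation-dilution model of a stable fluorescent transcriptional reporter.

A stable fluorophore (e.g., sfGFP driven from a pheromone-gene promoter)
integrates synthesis over time, so its level does not track the synthesis
rate directly.  This module models the immature protein ``P`` and mature
fluorescent reporter ``R``:

.. math::

    dP/dt &= k_s(t) - k_m P - k_d P \\\\
    dR/dt &= k_m P - k_d R

with a square-wave synthesis rate ``k_s(t)`` equal to ``F`` during G1 (the
first ``g1_fraction`` of the cycle) and 1 otherwise, maturation rate ``k_m``
(0.123 per min for sfGFP) and dilution rate ``k_d`` (0.007 per min for a
100-min doubling time).  Because the system is linear with piecewise-constant
input, the periodic steady state over one cell cycle has a closed form
(matrix-exponential fixed point), which doubles as the built-in oracle for
the numerical integrator.

The observable is the *fractional change* of ``R`` over the cycle,
``(max R - min R) / R(bud emergence)``, matching how experimental traces are
normalised to the value at the time of first bud emergence.  Inverting the
monotone map from fold-change ``F`` to fractional change tells how large a
synthesis-rate oscillation must be to produce an observed fluorescence
fluctuation; a 20% fluctuation requires more than a 5-fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq

from .errors import FitError, ParameterError

Normalizer = Literal["bud_emergence", "min", "mean"]


@dataclass(frozen=True)
class ReporterParams:
    """Reporter-model parameters (rates per minute, times in minutes)."""

    fold_change: float = 1.0
    k_m: float = 0.123
    k_d: float = 0.007
    cycle_length: float = 100.0
    g1_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ParameterError("fold_change must be >= 1")
        if self.k_m <= 0 or self.k_d <= 0 or self.cycle_length <= 0:
            raise ParameterError("rates and cycle length must be positive")
        if not 0.0 < self.g1_fraction < 1.0:
            raise ParameterError("g1_fraction must lie in (0, 1)")

    @property
    def t_g1(self) -> float:
        """Duration of G1 (synthesis at F), placed at the start of the cycle."""
        return self.g1_fraction * self.cycle_length

    @property
    def matrix(self) -> NDArray[np.float64]:
        return np.array(
            [[-(self.k_m + self.k_d), 0.0], [self.k_m, -self.k_d]]
        )


@dataclass(frozen=True)
class ReporterTrace:
    """One cell cycle of the reporter model at periodic steady state."""

    times: NDArray[np.float64]
    P: NDArray[np.float64]
    R: NDArray[np.float64]
    in_g1: NDArray[np.bool_]
    params: ReporterParams

    @property
    def r_at_bud_emergence(self) -> float:
        """R at the G1 -> S/G2/M transition (t = t_g1, included in the grid)."""
        idx = int(np.argmin(np.abs(self.times - self.params.t_g1)))
        return float(self.R[idx])


def _phase_affine(params: ReporterParams, ks: float, t: float):
    """Propagator (E, c) of x' = Ax + b over time t: x(t) = E x0 + c."""
    a = params.matrix
    e = expm(a * t)
    b = np.array([ks, 0.0])
    c = np.linalg.solve(a, (e - np.eye(2)) @ b)
    return e, c


def periodic_cycle_start(params: ReporterParams) -> NDArray[np.float64]:
    """Closed-form (P, R) at the start of G1 at periodic steady state.

    Composes the affine phase propagators over one cycle and solves for the
    fixed point of the resulting affine map.
    """
    e1, c1 = _phase_affine(params, params.fold_change, params.t_g1)
    e2, c2 = _phase_affine(params, 1.0, params.cycle_length - params.t_g1)
    m = e2 @ e1
    c = e2 @ c1 + c2
    return np.linalg.solve(np.eye(2) - m, c)


def _integrate_cycle(
    params: ReporterParams, x0: NDArray[np.float64], n_points: int, rtol: float
) -> ReporterTrace:
    t_g1, t_cyc = params.t_g1, params.cycle_length
    a = params.matrix

    def rhs(_t, x, ks):
        return a @ x + np.array([ks, 0.0])

    n1 = max(int(round(n_points * params.g1_fraction)), 2)
    t1 = np.linspace(0.0, t_g1, n1)
    t2 = np.linspace(t_g1, t_cyc, n_points - n1 + 1)
    sol1 = solve_ivp(
        rhs, (0.0, t_g1), x0, t_eval=t1, args=(params.fold_change,),
        rtol=rtol, atol=1e-12, method="LSODA",
    )
    sol2 = solve_ivp(
        rhs, (t_g1, t_cyc), sol1.y[:, -1], t_eval=t2, args=(1.0,),
        rtol=rtol, atol=1e-12, method="LSODA",
    )
    times = np.concatenate([sol1.t, sol2.t[1:]])
    y = np.concatenate([sol1.y, sol2.y[:, 1:]], axis=1)
    return ReporterTrace(
        times=times, P=y[0], R=y[1], in_g1=times <= t_g1, params=params
    )


def simulate_reporter(
    params: ReporterParams,
    n_cycles: int = 200,
    solver_tol: float = 1e-9,
    n_points: int = 601,
) -> ReporterTrace:
    """Integrate to periodic steady state and return the final cycle.

    Cycles are integrated from a zero initial state until the state at the
    cycle boundary moves by less than ``solver_tol`` (relative) between
    successive cycles; raises :class:`FitError` on non-convergence.
    """
    e1, c1 = _phase_affine(params, params.fold_change, params.t_g1)
    e2, c2 = _phase_affine(
        params, 1.0, params.cycle_length - params.t_g1
    )
    x = np.zeros(2)
    for _ in range(n_cycles):
        x_next = e2 @ (e1 @ x + c1) + c2
        if np.max(np.abs(x_next - x)) <= solver_tol * max(np.max(np.abs(x_next)), 1e-30):
            x = x_next
            break
        x = x_next
    else:
        raise FitError(f"periodic steady state not reached in {n_cycles} cycles")
    return _integrate_cycle(params, x, n_points, rtol=min(solver_tol, 1e-9))


def analytic_trace(params: ReporterParams, n_points: int = 601) -> ReporterTrace:
    """Trace of the closed-form periodic steady state (oracle path)."""
    x0 = periodic_cycle_start(params)
    return _integrate_cycle(params, x0, n_points, rtol=1e-12)


def fractional_change(
    trace: ReporterTrace, normalizer: Normalizer = "bud_emergence"
) -> float:
    """Peak-to-trough excursion of R, normalised.

    Default normaliser is R at bud emergence (the G1 -> S/G2/M transition),
    matching the experimental normalisation to the first-bud-emergence time
    point; ``min`` and ``mean`` are available as alternatives.
    """
    r = np.asarray(trace.R)
    if np.max(np.abs(r)) <= 0:
        raise ParameterError("degenerate all-zero trace")
    denom = {
        "bud_emergence": trace.r_at_bud_emergence,
        "min": float(r.min()),
        "mean": float(r.mean()),
    }[normalizer]
    if denom <= 0:
        raise ParameterError("normaliser is non-positive")
    return float((r.max() - r.min()) / denom)


def required_fold_change(
    target_change: float = 0.2,
    params: ReporterParams | None = None,
    normalizer: Normalizer = "bud_emergence",
    bracket: tuple[float, float] = (1.0, 100.0),
    rtol: float = 1e-3,
    n_points: int = 1201,
) -> float:
    """Smallest fold-change F whose fractional change reaches the target.

    The map F -> fractional change is strictly increasing (zero at F = 1),
    so the root is found by bracketed root-finding on the closed-form
    periodic steady state.
    """
    if params is None:
        params = ReporterParams()
    if target_change == 0:
        return 1.0
    if target_change < 0:
        raise ParameterError("target_change must be >= 0")

    def fc(f: float) -> float:
        p = ReporterParams(
            fold_change=f, k_m=params.k_m, k_d=params.k_d,
            cycle_length=params.cycle_length, g1_fraction=params.g1_fraction,
        )
        return fractional_change(analytic_trace(p, n_points), normalizer)

    lo, hi = bracket
    if fc(hi) < target_change:
        raise ParameterError(
            f"target {target_change} unreachable within F <= {hi} "
            f"(max fractional change {fc(hi):.4f})"
        )
    return float(brentq(lambda f: fc(f) - target_change, lo, hi, rtol=rtol))
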