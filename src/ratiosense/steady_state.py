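"""Closed-form steady-state model of active G protein under ratiometric and
nonratiometric inactivation.

The model considers a fixed pool of membrane G protein exposed to a linear
gradient of receptor occupancy ``f(x)`` across the cell.  Activation is
proportional to the local concentration of ligand-bound (active) receptor.
The two models differ only in how active G protein is switched off:

* **ratiometric** — inactivation is catalysed by *unoccupied* receptor
  (receptor-tethered RGS), so the inactivation rate is proportional to
  ``1 - f``.  At steady state the active fraction is

  .. math:: g^*(f) = \\frac{f}{f + \\beta (1 - f)}

* **nonratiometric** — inactivation is a first-order process with a single
  spatially uniform rate constant.  The rate is matched to the ratiometric
  model at the gradient midpoint (50% occupancy by default), giving

  .. math:: g^*(f) = \\frac{f}{f + \\beta/2}

``beta`` is the ratio of the inactivation to the activation rate constant.
When ``beta = 1`` the ratiometric G-protein gradient reproduces the receptor
gradient exactly; ``beta > 1`` makes it convex (steeper near the up-gradient
pole), ``beta < 1`` concave.  The nonratiometric profile is concave for every
``beta``.

The headline statistic is the Signal Ratio (SR): the cross-cell difference in
active G protein predicted by the ratiometric model divided by that of the
matched nonratiometric model.  SR tends to 2 for vanishingly shallow
gradients and grows with both steepness and ``beta`` (at full steepness
``SR = (2 + beta)/2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import ParameterError

Model = Literal["ratiometric", "nonratiometric"]

_MODELS = ("ratiometric", "nonratiometric")


@dataclass(frozen=True)
class SteadyStateParams:
    """Parameters of the matched steady-state gradient models.

    Parameters
    ----------
    beta:
        Ratio of G-protein inactivation to activation rate constants (> 0).
    steepness:
        Dimensionless gradient steepness sigma in [0, 1]: the slope of the
        receptor-occupancy gradient normalised to the maximal linear gradient
        spanning 0-100% occupancy across the cell.
    cell_width:
        Width of the cell along the gradient axis, in micrometres.
    midpoint_occupancy:
        Receptor occupancy at the cell midpoint (the matching point of the
        two models).
    """

    beta: float
    steepness: float
    cell_width: float = 5.0
    midpoint_occupancy: float = 0.5

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        if not 0.0 <= self.steepness <= 1.0:
            raise ParameterError(
                f"steepness must lie in [0, 1], got {self.steepness}"
            )
        if not self.cell_width > 0:
            raise ParameterError(f"cell_width must be > 0, got {self.cell_width}")
        if not 0.0 < self.midpoint_occupancy < 1.0:
            raise ParameterError(
                f"midpoint_occupancy must lie in (0, 1), got {self.midpoint_occupancy}"
            )
        for x in (0.0, self.cell_width):
            f = self.midpoint_occupancy + self.steepness * (x / self.cell_width - 0.5)
            if f < -1e-12 or f > 1 + 1e-12:
                raise ParameterError(
                    "occupancy gradient leaves [0, 1] within the cell: "
                    f"f({x}) = {f}"
                )

    def occupancy(self, x: ArrayLike) -> NDArray[np.float64] | float:
        """Receptor occupancy f(x) at position(s) x in [0, cell_width]."""
        x = np.asarray(x, dtype=float)
        f = self.midpoint_occupancy + self.steepness * (x / self.cell_width - 0.5)
        return np.clip(f, 0.0, 1.0)


@dataclass(frozen=True)
class GProfile:
    """Sampled steady-state profile of active G protein along the gradient."""

    positions: NDArray[np.float64]
    g_star: NDArray[np.float64]
    model: Model

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        g = np.asarray(self.g_star, dtype=float)
        if pos.shape != g.shape:
            raise ParameterError("positions and g_star must have equal shape")
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ParameterError("g_star values must lie in [0, 1]")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "g_star", g)


def _check_domain(f: ArrayLike, beta: float) -> NDArray[np.float64]:
    if not np.isfinite(beta) or beta <= 0:
        raise ParameterError(f"beta must be a positive finite number, got {beta}")
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ParameterError("receptor occupancy f must lie in [0, 1]")
    return arr


def g_ratiometric(f: ArrayLike, beta: float) -> NDArray[np.float64] | float:
    """Steady-state active-G fraction with receptor-coupled inactivation.

    ``g = f / (f + beta * (1 - f))``; g(0) = 0, g(1) = 1, strictly increasing
    in f and decreasing in beta on (0, 1).
    """
    arr = _check_domain(f, beta)
    denom = arr + beta * (1.0 - arr)
    out = np.divide(arr, denom, out=np.zeros_like(arr), where=denom > 0)
    return out if out.ndim else float(out)


def g_nonratiometric(f: ArrayLike, beta: float) -> NDArray[np.float64] | float:
    """Steady-state active-G fraction with uniform first-order inactivation.

    The inactivation rate is matched to the ratiometric model at 50%
    occupancy, which fixes ``g = f / (f + beta / 2)``.
    """
    arr = _check_domain(f, beta)
    out = arr / (arr + beta / 2.0)
    return out if out.ndim else float(out)


_G_FUNCS = {"ratiometric": g_ratiometric, "nonratiometric": g_nonratiometric}


def gradient_profile(
    params: SteadyStateParams, model: Model, n_points: int = 101
) -> GProfile:
    """Sample the steady-state active-G profile at n evenly spaced positions."""
    if model not in _MODELS:
        raise ParameterError(f"model must be one of {_MODELS}, got {model!r}")
    if n_points < 2:
        raise ParameterError("n_points must be at least 2")
    x = np.linspace(0.0, params.cell_width, n_points)
    g = _G_FUNCS[model](params.occupancy(x), params.beta)
    return GProfile(positions=x, g_star=np.asarray(g), model=model)


def delta_g(params: SteadyStateParams, model: Model) -> float:
    """Difference in active-G fraction across the cell width.

    ``delta_g = g(f(cell_width)) - g(f(0))``; non-negative for an increasing
    occupancy gradient and zero for a flat one.
    """
    if model not in _MODELS:
        raise ParameterError(f"model must be one of {_MODELS}, got {model!r}")
    g = _G_FUNCS[model]
    f_lo = float(params.occupancy(0.0))
    f_hi = float(params.occupancy(params.cell_width))
    return float(g(f_hi, params.beta) - g(f_lo, params.beta))


def signal_ratio(params: SteadyStateParams) -> float:
    """Signal Ratio: ratiometric over nonratiometric cross-cell difference.

    SR > 1 means the ratiometric model converts the same receptor gradient
    into a larger active-G difference.  SR tends to 2 as steepness tends to
    zero, for every beta.
    """
    if params.steepness <= 0:
        raise ParameterError("signal_ratio is undefined for steepness = 0")
    return delta_g(params, "ratiometric") / delta_g(params, "nonratiometric")


def profile_curvature(
    profile: GProfile, rel_tol: float = 1e-10
) -> Literal["convex", "concave", "linear", "indeterminate"]:
    """Classify a sampled profile by the sign of its second differences.

    Second differences smaller than ``rel_tol * max|g|`` are treated as zero.
    Profiles whose non-zero second differences mix signs are reported as
    ``"indeterminate"`` rather than raising.
    """
    g = np.asarray(profile.g_star, dtype=float)
    if g.size < 5:
        raise ParameterError("curvature needs a profile of at least 5 points")
    dx = np.diff(profile.positions)
    if not np.allclose(dx, dx[0], rtol=1e-8):
        raise ParameterError("curvature requires evenly spaced positions")
    d2 = np.diff(g, n=2)
    tol = rel_tol * max(np.max(np.abs(g)), 1e-300)
    pos = d2 > tol
    neg = d2 < -tol
    if not pos.any() and not neg.any():
        return "linear"
    if pos.any() and neg.any():
        return "indeterminate"
    return "convex" if pos.any() else "concave"


def upgradient_fraction(
    params: SteadyStateParams, model: Model, quantile: float = 0.2, n_points: int = 1001
) -> float:
    """Fraction of total cross-cell active G in the up-gradient end of the cell.

    Integrates the steady-state profile over the top ``quantile`` of the cell
    width and divides by the integral over the whole width.  A convex profile
    concentrates a larger share of active G near the up-gradient pole, which
    is the proposed advantage for choosing a polarity site.
    """
    prof = gradient_profile(params, model, n_points=n_points)
    x, g = prof.positions, prof.g_star
    total = np.trapezoid(g, x)
    if total <= 0:
        return float("nan")
    cut = (1.0 - quantile) * params.cell_width
    mask = x >= cut
    top = np.trapezoid(g[mask], x[mask])
    return float(top / total)
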