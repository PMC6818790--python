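"""Independent numerical oracles used to freeze expected values.

These integrate the mass-action kinetics directly with scipy's ODE solver,
independent of the closed-form expressions in the package, so the two
routes cross-check each other.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def g_ratiometric_ode(f: float, beta: float, t_end: float = 5000.0) -> float:
    """Steady state of dG/dt = f(1-G) - beta*(1-f)*G by integration."""

    def rhs(_t, g):
        return f * (1.0 - g) - beta * (1.0 - f) * g

    sol = solve_ivp(rhs, (0.0, t_end), [0.5], rtol=1e-10, atol=1e-12)
    return float(sol.y[0, -1])


def g_nonratiometric_ode(f: float, beta: float, t_end: float = 5000.0) -> float:
    """Steady state of dG/dt = f(1-G) - (beta/2)*G by integration."""

    def rhs(_t, g):
        return f * (1.0 - g) - (beta / 2.0) * g

    sol = solve_ivp(rhs, (0.0, t_end), [0.5], rtol=1e-10, atol=1e-12)
    return float(sol.y[0, -1])


def ks_statistic_brute(a, b) -> float:
    """O(n*m) sup-difference of the two empirical CDFs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        d = abs((a <= x).mean() - (b <= x).mean())
        best = max(best, d)
    return best
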