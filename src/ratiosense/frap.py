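"""FRAP-based estimation of membrane diffusion coefficients.

Fluorescence recovery after photobleaching: a sub-region of the cell is
bleached and its fluorescence recovery by diffusion is tracked (15-s frames
over 10 min by default).  The analysis chain is

1. :func:`normalize_trace` — divide the bleach-region signal by the
   whole-cell signal frame by frame, cancelling acquisition photobleaching;
2. :func:`fit_exponential` — least-squares fit of
   ``f(t) = f_inf - (f_inf - f0) * exp(-k t)`` from the first post-bleach
   frame, a three-parameter form that accommodates an immobile fraction
   (``f_inf`` below the pre-bleach level);
3. :func:`soumpasis_diffusion` — convert the recovery rate to a diffusion
   coefficient via the circular-spot half-time relation
   ``D = 0.224 * w**2 / t_half`` with ``t_half = ln(2) / k``.

The exponential is an approximation to the full Bessel-function recovery
curve, so recovered D carries a bounded systematic bias; ordering between
conditions (e.g., receptor-like vs v-SNARE-like mobility) is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError

#: Soumpasis half-time constant for a circular bleach spot: D = C * w^2 / t_half.
SOUMPASIS_CONSTANT = 0.224


@dataclass(frozen=True)
class FRAPTrace:
    """Bleach-region and whole-cell fluorescence time series.

    ``n_prebleach`` frames (if any) precede the bleach; the first
    post-bleach frame is ``times[n_prebleach]``.
    """

    times: NDArray[np.float64]
    bleach_signal: NDArray[np.float64]
    cell_signal: NDArray[np.float64]
    bleach_radius: float = 1.0
    n_prebleach: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.bleach_signal, dtype=float)
        c = np.asarray(self.cell_signal, dtype=float)
        if not (t.shape == b.shape == c.shape):
            raise ParameterError("times and signals must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(b < 0) or np.any(c < 0):
            raise ParameterError("signals must be >= 0")
        if self.bleach_radius <= 0:
            raise ParameterError("bleach_radius must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "bleach_signal", b)
        object.__setattr__(self, "cell_signal", c)


@dataclass(frozen=True)
class FRAPFit:
    """Exponential recovery fit and derived diffusion coefficient."""

    k: float  # recovery rate constant, 1/s
    f0: float  # level immediately post-bleach
    f_inf: float  # recovery plateau
    residual: float  # RMS residual of the fit
    t_half: float
    diffusion: float | None = None  # um^2/s, set by soumpasis_diffusion


def normalize_trace(trace: FRAPTrace) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Per-frame ratio of bleach-region to whole-cell signal.

    Dividing by the whole-cell total at each time point cancels the
    progressive loss of fluorescence caused by image acquisition itself,
    leaving the redistribution dynamics.  Returns ``(times, normalized)``.
    """
    if np.any(trace.cell_signal <= 0):
        raise ParameterError("whole-cell signal must be > 0 at every frame")
    return trace.times, trace.bleach_signal / trace.cell_signal


def fit_exponential(
    times: NDArray[np.float64],
    values: NDArray[np.float64],
    start_index: int | None = None,
) -> FRAPFit:
    """Least-squares exponential recovery fit from the first post-bleach frame.

    ``start_index`` marks the first post-bleach sample; by default the
    minimum of the trace is used.  Requires at least 10 post-bleach points.
    Raises :class:`FitError` when the optimiser fails or the recovery rate
    is unidentifiable (flat trace).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if start_index is None:
        start_index = int(np.argmin(y))
    t = t[start_index:] - t[start_index]
    y = y[start_index:]
    if t.size < 10:
        raise ParameterError("need at least 10 post-bleach points")
    spread = float(y.max() - y.min())
    if spread <= 0 or spread < 1e-12 * max(abs(float(y.mean())), 1.0):
        raise FitError("flat trace: recovery rate is unidentifiable")

    def model(tt, f_inf, f0, k):
        return f_inf - (f_inf - f0) * np.exp(-k * tt)

    p0 = (float(y[-5:].mean()), float(y[0]), math.log(2.0) / max(t[-1] / 4.0, t[1]))
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([0.0, 0.0, 1e-8], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    f_inf, f0, k = map(float, popt)
    if f_inf < f0:
        raise FitError("fitted plateau below post-bleach level; not a recovery")
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return FRAPFit(k=k, f0=f0, f_inf=f_inf, residual=resid, t_half=math.log(2.0) / k)


def soumpasis_diffusion(
    fit: FRAPFit, w: float, constant: float = SOUMPASIS_CONSTANT
) -> FRAPFit:
    """Convert a recovery rate to a diffusion coefficient.

    ``D = constant * w**2 / t_half`` for a circular bleach spot of radius
    ``w`` (um); ``t_half = ln 2 / k``.  Returns a copy of the fit with
    ``diffusion`` set.
    """
    if fit.k <= 0:
        raise ParameterError("recovery rate must be > 0")
    if w <= 0:
        raise ParameterError("bleach radius must be > 0")
    d = constant * w**2 / fit.t_half
    return FRAPFit(
        k=fit.k, f0=fit.f0, f_inf=fit.f_inf, residual=fit.residual,
        t_half=fit.t_half, diffusion=d,
    )


def estimate_diffusion(trace: FRAPTrace) -> FRAPFit:
    """Full pipeline: normalise, fit the recovery, convert to D."""
    t, norm = normalize_trace(trace)
    start = trace.n_prebleach if trace.n_prebleach > 0 else None
    fit = fit_exponential(t, norm, start_index=start)
    return soumpasis_diffusion(fit, trace.bleach_radius)
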