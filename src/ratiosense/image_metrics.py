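"""Image statistics for polarity clustering, MAPK activity and receptor
distribution.

Three bespoke measurements used throughout the analysis of yeast mating
movies:

* **Clustering parameter (CP)** — a deviation-from-uniformity statistic on
  the cumulative distribution of pixel intensities within a cell ROI.
  Intensities are min-max normalised to [0, 1]; the empirical CDF ``D_i`` is
  compared with the uniform CDF ``U_i = i`` at 500 evenly spaced levels and
  ``CP = 2 * mean(D_i - U_i)``, clipped to [0, 1].  A small bright patch with
  sharp edges pushes most pixels below every level, so CP approaches 1; a
  uniform intensity spread gives CP near 0.  CP is exactly invariant under
  affine intensity rescaling.

* **MAPK activity metric** — the coefficient of variation (CV) of in-ROI
  pixel intensities approximates the nuclear-to-cytoplasmic ratio of a
  nuclear-export MAPK sensor.  CV falls as MAPK activity rises, so activity
  is scored as ``m_t = 2 - CV_t / CV_ref`` with the reference CV taken at
  the frame before cell fusion (m = 1 there).

* **Membrane linescans** — intensity profiles along the cell contour,
  background-subtracted and normalised (to unit integral, or to percent of
  maximum), optionally centred on the peak of a smoothed fit and averaged
  across cells; the side-to-side receptor asymmetry is summarised as the
  ratio of the mean intensity over the half-contour centred on the peak to
  the mean over the opposite half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.interpolate import splev, splrep

from .errors import ParameterError


@dataclass
class CellImage:
    """2D intensity array with a boolean in-cell ROI mask."""

    intensity: NDArray[np.float64]
    roi_mask: NDArray[np.bool_]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.intensity.shape != self.roi_mask.shape:
            raise ParameterError("intensity and roi_mask shapes differ")
        if not self.roi_mask.any():
            raise ParameterError("ROI mask is empty")
        vals = self.intensity[self.roi_mask]
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ParameterError("in-ROI intensities must be finite and >= 0")

    @property
    def roi_values(self) -> NDArray[np.float64]:
        return self.intensity[self.roi_mask]


@dataclass(frozen=True)
class CPResult:
    """Clustering parameter and its provenance."""

    cp: float
    n_pixels: int
    levels: int
    degenerate: bool = False


@dataclass(frozen=True)
class CVSeries:
    """Per-frame coefficient of variation of in-ROI pixel intensities."""

    times: NDArray[np.float64]
    cv: NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "cv", np.asarray(self.cv, dtype=float))
        if self.times.shape != self.cv.shape:
            raise ParameterError("times and cv must have equal length")
        if np.any(self.cv < 0):
            raise ParameterError("cv values must be >= 0")


@dataclass
class Linescan:
    """Closed-contour membrane intensity profile.

    ``positions`` are arc positions (or angles) along the contour; the
    profile is periodic: the last sample wraps around to the first.
    """

    positions: NDArray[np.float64]
    intensity: NDArray[np.float64]
    background: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.shape != self.intensity.shape:
            raise ParameterError("positions and intensity must match")
        if not np.all(np.isfinite(self.intensity)):
            raise ParameterError("intensities must be finite")


def max_project(stack: ArrayLike) -> NDArray[np.float64]:
    """Maximum projection of a (planes, y, x) stack over planes."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ParameterError("stack must be 3-dimensional (planes, y, x)")
    return arr.max(axis=0)


def clustering_parameter(
    image: CellImage,
    levels: int = 500,
    quadrature: Literal["mean", "trapezoid"] = "mean",
) -> CPResult:
    """Deviation-from-uniformity (CP) of in-ROI pixel intensities.

    With raw intensities p min-max normalised to i in [0, 1], the empirical
    CDF ``D(i) = #(pixels with intensity < i) / n`` is evaluated at levels
    ``i_n = n / levels`` (n = 1..levels) and CP is twice the quadrature
    approximation of the integral of ``D(i) - i``, clipped to [0, 1].

    A constant image has no intensity distribution to score; CP is defined
    as 0 and flagged degenerate.
    """
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    vals = image.roi_values
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return CPResult(cp=0.0, n_pixels=vals.size, levels=levels, degenerate=True)
    norm = np.sort((vals - lo) / (hi - lo))
    grid = np.arange(1, levels + 1) / levels
    # D(i) with strict inequality: count of values < i
    d = np.searchsorted(norm, grid, side="left") / norm.size
    excess = d - grid
    if quadrature == "mean":
        integral = float(excess.mean())
    elif quadrature == "trapezoid":
        integral = float(np.trapezoid(excess, grid)) / (grid[-1] - grid[0])
    else:
        raise ParameterError(f"unknown quadrature {quadrature!r}")
    return CPResult(
        cp=float(np.clip(2.0 * integral, 0.0, 1.0)),
        n_pixels=vals.size,
        levels=levels,
    )


def coefficient_of_variation(image: CellImage) -> float:
    """CV (SD / mean) of in-ROI pixel intensities."""
    vals = image.roi_values
    mean = vals.mean()
    if mean <= 0:
        raise ParameterError("CV undefined for zero-mean ROI")
    return float(vals.std() / mean)


def cv_series(images: Sequence[CellImage], times: ArrayLike | None = None) -> CVSeries:
    """Per-frame CV of a sequence of cell images."""
    cvs = np.array([coefficient_of_variation(im) for im in images])
    t = np.arange(len(cvs), dtype=float) if times is None else np.asarray(times, float)
    return CVSeries(times=t, cv=cvs)


def mapk_activity(series: CVSeries, reference_index: int = -1) -> NDArray[np.float64]:
    """MAPK activity metric ``m_t = 2 - CV_t / CV_ref``.

    ``reference_index`` selects the normalisation frame (default: the last
    frame, i.e. the time point before fusion for a trace ending at fusion).
    m = 1 at the reference frame; higher m means a more uniform sensor
    distribution, i.e. higher MAPK activity.
    """
    cv_ref = float(series.cv[reference_index])
    if cv_ref <= 0:
        raise ParameterError("reference CV must be > 0")
    return 2.0 - series.cv / cv_ref


def normalize_linescan(
    ls: Linescan, mode: Literal["integral_one", "percent_max"] = "integral_one"
) -> Linescan:
    """Background-subtract and normalise a linescan.

    ``integral_one`` scales the background-subtracted trace to a trapezoidal
    integral of 1 over the closed contour (the wrap-around segment included);
    ``percent_max`` scales so the maximum is 100.
    """
    corrected = ls.intensity - ls.background
    if np.max(corrected) <= 0:
        raise ParameterError("trace is all background")
    if mode == "percent_max":
        scaled = corrected / corrected.max() * 100.0
    elif mode == "integral_one":
        pos = ls.positions
        period = (pos[-1] - pos[0]) * len(pos) / (len(pos) - 1)
        # trapezoid over the closed contour, including the wrap segment
        closed_pos = np.append(pos, pos[0] + period)
        closed_val = np.append(corrected, corrected[0])
        integral = float(np.trapezoid(closed_val, closed_pos))
        if integral <= 0:
            raise ParameterError("non-positive integral after background subtraction")
        scaled = corrected / integral
    else:
        raise ParameterError(f"unknown normalisation mode {mode!r}")
    return Linescan(positions=ls.positions.copy(), intensity=scaled, background=0.0)


def smooth_periodic(ls: Linescan, smoothing: float = 0.75) -> NDArray[np.float64]:
    """Periodic smoothing-spline fit evaluated at the sample positions.

    ``smoothing`` plays the role of a spline smoothing factor in [0, 1]:
    0 interpolates, larger values smooth more.  The residual budget passed
    to the spline is ``smoothing * n * var(intensity)``.
    """
    if not 0.0 <= smoothing <= 1.0:
        raise ParameterError("smoothing must lie in [0, 1]")
    y = ls.intensity
    n = y.size
    if n < 8:
        raise ParameterError("need at least 8 samples for a periodic spline")
    x = np.arange(n + 1, dtype=float)
    s = smoothing * n * float(np.var(y))
    tck = splrep(x, np.append(y, y[0]), per=1, s=s, k=3)
    return np.asarray(splev(x[:-1], tck))


@dataclass(frozen=True)
class LinescanAverage:
    """Pointwise mean and SD of peak-centred linescans."""

    positions: NDArray[np.float64]
    mean: NDArray[np.float64]
    sd: NDArray[np.float64]
    tie_flagged: bool = False


def average_centered_linescans(
    scans: Sequence[Linescan], smoothing: float = 0.75
) -> LinescanAverage:
    """Centre each scan on its smoothed-profile peak, then average.

    Each (already normalised) scan is circularly rotated so that the maximum
    of its smoothed profile sits at the centre index; the pointwise mean and
    SD across scans are returned.  Ties among smoothed maxima break to the
    first occurrence and set ``tie_flagged``.
    """
    if len(scans) < 2:
        raise ParameterError("need at least 2 linescans to average")
    n = scans[0].intensity.size
    if any(s.intensity.size != n for s in scans):
        raise ParameterError("all linescans must share the same sampling")
    center = n // 2
    tie = False
    aligned = np.empty((len(scans), n))
    for j, ls in enumerate(scans):
        smooth = smooth_periodic(ls, smoothing)
        peaks = np.flatnonzero(np.isclose(smooth, smooth.max(), rtol=1e-12))
        if peaks.size > 1:
            tie = True
        aligned[j] = np.roll(ls.intensity, center - int(peaks[0]))
    return LinescanAverage(
        positions=scans[0].positions.copy(),
        mean=aligned.mean(axis=0),
        sd=aligned.std(axis=0, ddof=1),
        tie_flagged=tie,
    )


def asymmetry_fold(profile: Linescan | ArrayLike) -> float:
    """Side-to-side fold asymmetry of a closed-contour profile.

    The half-contour with the largest mean intensity (for a single-peak
    profile: the half centred on the peak) is compared with the opposite
    half: fold = mean(brightest half) / mean(opposite half), >= 1 by
    construction.  A non-positive opposite-half mean returns ``inf``.
    Invariant to circular rotation of the start point.
    """
    y = profile.intensity if isinstance(profile, Linescan) else np.asarray(profile, float)
    n = y.size
    if n < 4:
        raise ParameterError("profile too short")
    half = n // 2
    # circular window sums of length n//2 at every start position
    ext = np.concatenate([y, y])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    window = csum[half : half + n] - csum[:n]
    start = int(np.argmax(window))
    bright = window[start] / half
    rest = (y.sum() - window[start]) / (n - half)
    if rest <= 0:
        return float("inf")
    return float(bright / rest)
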