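"""Orientation and timing statistics for mating-cell timelines.

Mating yeast cells form an initial polarity cluster shortly after birth,
wander through an "indecisive phase" until the cluster stabilises
(commitment), and then fuse with a partner.  This module scores:

* the orientation of the initial cluster — the unsigned planar angle between
  the cell-centre-to-cluster line and the cell-centre-to-reference line
  (reference: nearest eligible partner, or the previous division site);
* angle histograms in 30-degree segments (a random process puts ~17% of
  cells in each of the six segments);
* phase durations — indecisive (initial clustering to stable polarization)
  and committed (stable polarization to fusion);
* two-sample Kolmogorov-Smirnov comparisons between strata (first- vs
  second-born cells, genotypes, well- vs poorly-oriented cells).

Timelines are tidy :class:`pandas.DataFrame` tables with one row per cell;
see :data:`TIMELINE_COLUMNS` for the schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from .errors import ParameterError, ValidationError

#: Column schema of a mating-timeline table (one row per cell).  Coordinate
#: columns are 2D image-plane positions; times share one clock (minutes).
TIMELINE_COLUMNS = (
    "cell_id",
    "pair_id",
    "born_order",  # "first" | "second"
    "mating_type",
    "t_birth",
    "t_ic",  # initial clustering
    "t_p",  # stable polarization (commitment)
    "t_fusion",
    "cell_x",
    "cell_y",
    "cluster_x",
    "cluster_y",
    "partner_x",
    "partner_y",
    "neck_x",
    "neck_y",
)

SEGMENT_WIDTH = 30.0


def orientation_angle(
    cell_center: Sequence[float],
    cluster_centroid: Sequence[float],
    reference_point: Sequence[float],
) -> float:
    """Unsigned planar angle (degrees, [0, 180]) at the cell centre.

    The angle between the line from the cell centre to the cluster centroid
    and the line from the cell centre to the reference point (partner
    surface or previous division site).  Invariant under global rotation
    and translation.
    """
    c = np.asarray(cell_center, dtype=float)
    v1 = np.asarray(cluster_centroid, dtype=float) - c
    v2 = np.asarray(reference_point, dtype=float) - c
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ParameterError("cluster or reference point coincides with the cell centre")
    cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


@dataclass(frozen=True)
class SegmentHistogram:
    """Counts and percentages of angles per angular segment."""

    edges: NDArray[np.float64]
    counts: NDArray[np.int64]
    percentages: NDArray[np.float64]
    n: int


def segment_histogram(angles: ArrayLike, width: float = SEGMENT_WIDTH) -> SegmentHistogram:
    """Group angles into half-open segments [0, w), [w, 2w), ... [180-w, 180].

    The final segment is closed so that an angle of exactly 180 degrees is
    counted.  Percentages sum to 100 exactly (up to float rounding of the
    division, not of the counts).
    """
    arr = np.asarray(angles, dtype=float)
    if arr.size == 0:
        raise ParameterError("no angles to histogram")
    if np.any(arr < 0) or np.any(arr > 180):
        raise ParameterError("angles must lie in [0, 180]")
    if not (0 < width <= 180) or 180.0 % width:
        raise ParameterError("segment width must divide 180")
    edges = np.arange(0.0, 180.0 + width / 2, width)
    counts, _ = np.histogram(arr, bins=edges)  # numpy closes the last bin
    return SegmentHistogram(
        edges=edges,
        counts=counts.astype(np.int64),
        percentages=counts / arr.size * 100.0,
        n=arr.size,
    )


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def ks_two_sample(sample_a: ArrayLike, sample_b: ArrayLike) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum of the absolute difference between the two empirical
    CDFs; the p-value comes from the asymptotic Kolmogorov distribution at
    the effective sample size.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        n_a=a.size, n_b=b.size,
    )


def ks_vs_uniform(angles: ArrayLike, high: float = 180.0) -> KSResult:
    """One-sample KS test of angles against the uniform null on [0, high].

    The uniform-in-the-imaging-plane null is the reference "random
    orientation" model (each 30-degree segment expects 1/6 of cells).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ParameterError("sample must be nonempty")
    res = stats.kstest(a, stats.uniform(loc=0, scale=high).cdf)
    return KSResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        n_a=a.size, n_b=0,
    )


def timeline_angles(
    timelines: pd.DataFrame, reference: str = "partner"
) -> pd.Series:
    """Initial-cluster orientation angle per cell, against partner or neck."""
    if reference not in ("partner", "neck"):
        raise ParameterError("reference must be 'partner' or 'neck'")
    rx, ry = f"{reference}_x", f"{reference}_y"
    out = [
        orientation_angle(
            (row["cell_x"], row["cell_y"]),
            (row["cluster_x"], row["cluster_y"]),
            (row[rx], row[ry]),
        )
        for _, row in timelines.iterrows()
    ]
    return pd.Series(out, index=timelines.index, name=f"angle_to_{reference}")


def phase_durations(timelines: pd.DataFrame) -> pd.DataFrame:
    """Indecisive (t_p - t_ic) and committed (t_fusion - t_p) durations.

    Raises :class:`ValidationError` naming the offending cells when event
    times are missing or out of order.
    """
    required = ["t_ic", "t_p", "t_fusion"]
    missing = [c for c in required if c not in timelines.columns]
    if missing:
        raise ValidationError(f"timeline lacks columns: {missing}")
    sub = timelines[required]
    bad_na = timelines.index[sub.isna().any(axis=1)]
    if len(bad_na):
        ids = _cell_ids(timelines, bad_na)
        raise ValidationError(f"missing event times for cells: {ids}")
    inverted = timelines.index[
        (sub["t_ic"] > sub["t_p"]) | (sub["t_p"] > sub["t_fusion"])
    ]
    if len(inverted):
        ids = _cell_ids(timelines, inverted)
        raise ValidationError(f"event times out of order for cells: {ids}")
    out = pd.DataFrame(index=timelines.index)
    if "cell_id" in timelines.columns:
        out["cell_id"] = timelines["cell_id"]
    out["indecisive"] = sub["t_p"] - sub["t_ic"]
    out["committed"] = sub["t_fusion"] - sub["t_p"]
    return out


def _cell_ids(timelines: pd.DataFrame, idx) -> list:
    if "cell_id" in timelines.columns:
        return timelines.loc[idx, "cell_id"].tolist()
    return list(idx)


def bias_analysis(
    timelines: pd.DataFrame,
    angle_threshold: float = 60.0,
    min_stratum: int = 5,
    reference: str = "partner",
) -> dict:
    """Stratified orientation-bias and timing analysis.

    For each born-order stratum with at least ``min_stratum`` cells: the
    angle sample, its 30-degree segment histogram, and a KS test against the
    uniform null.  Also compares first- vs second-born angle distributions
    and, when polarization/fusion times are present, the indecisive-phase
    durations of well-oriented (angle < threshold) vs misoriented cells.

    Undersized strata are skipped and listed under ``"skipped"``.
    """
    df = timelines.copy()
    df["angle"] = timeline_angles(df, reference=reference)
    result: dict = {"strata": {}, "skipped": [], "angle_threshold": angle_threshold}

    samples: dict[str, np.ndarray] = {}
    for order, grp in df.groupby("born_order"):
        if len(grp) < min_stratum:
            result["skipped"].append(str(order))
            continue
        angles = grp["angle"].to_numpy()
        samples[str(order)] = angles
        result["strata"][str(order)] = {
            "n": len(grp),
            "angles": angles,
            "median_angle": float(np.median(angles)),
            "segment_percentages": segment_histogram(angles).percentages,
            "ks_vs_uniform": ks_vs_uniform(angles),
        }
    if len(result["strata"]) < 2 and not result["skipped"]:
        raise ParameterError("need at least two strata with enough cells")

    if "first" in samples and "second" in samples:
        result["first_vs_second"] = ks_two_sample(samples["first"], samples["second"])

    has_times = df[["t_ic", "t_p", "t_fusion"]].notna().all(axis=1)
    if has_times.any():
        timed = df[has_times]
        durations = phase_durations(timed)
        well = durations.loc[timed["angle"] < angle_threshold, "indecisive"]
        mis = durations.loc[timed["angle"] >= angle_threshold, "indecisive"]
        if len(well) >= min_stratum and len(mis) >= min_stratum:
            result["indecisive_by_orientation"] = {
                "well_oriented_n": int(len(well)),
                "misoriented_n": int(len(mis)),
                "well_oriented_median": float(well.median()),
                "misoriented_median": float(mis.median()),
                "ks": ks_two_sample(well, mis),
            }
    return result
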