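"""Seeded synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here in place of
raw microscopy: cell images with a polarity cluster, nuclear/cytoplasmic
sensor images, membrane linescans with a prescribed side-to-side asymmetry,
FRAP recovery traces simulated by 2D diffusion at a known coefficient, and
mating-field timelines with tunable partner bias.  Each generator is a pure
function of its parameters and seed — identical calls give bit-identical
output — and each records the ground truth its downstream analysis is
expected to recover.

Default image geometry is 100 x 100 px at 0.1 um/px (a 10-um field around a
~5-um cell), echoing the microscope scale of the experiments being emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .errors import ParameterError
from .frap import FRAPTrace
from .geometry_stats import TIMELINE_COLUMNS
from .image_metrics import CellImage, Linescan

#: default image scale, micrometres per pixel
PIXEL_SIZE = 0.1


def _disk_mask(n_side: int, center: tuple[float, float], radius: float) -> NDArray[np.bool_]:
    yy, xx = np.mgrid[0:n_side, 0:n_side]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def gen_cluster_image(
    n_side: int = 100,
    signal_fraction: float = 0.5,
    spot_sigma: float = 3.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    spot_offset: float = 0.7,
) -> CellImage:
    """Round cell with a Gaussian polarity cluster at its edge.

    A disk ROI holds a uniform background plus a Gaussian spot (SD
    ``spot_sigma`` px) carrying ``signal_fraction`` of the total in-ROI
    intensity, centred at ``spot_offset`` x ROI-radius from the cell centre.
    Ground truth: the clustering parameter increases with ``signal_fraction``
    and decreases with ``spot_sigma``.
    """
    if not 0.0 <= signal_fraction < 1.0:
        raise ParameterError("signal_fraction must lie in [0, 1)")
    if spot_sigma <= 0:
        raise ParameterError("spot_sigma must be > 0")
    rng = np.random.default_rng(seed)
    c = (n_side - 1) / 2.0
    roi_r = 0.45 * n_side
    mask = _disk_mask(n_side, (c, c), roi_r)
    spot_c = (c + spot_offset * roi_r, c)
    if math.hypot(spot_c[0] - c, spot_c[1] - c) > roi_r:
        raise ParameterError("spot centre falls outside the ROI")
    img = np.zeros((n_side, n_side))
    img[mask] = 1.0
    if signal_fraction > 0:
        yy, xx = np.mgrid[0:n_side, 0:n_side]
        spot = np.exp(
            -((xx - spot_c[0]) ** 2 + (yy - spot_c[1]) ** 2) / (2 * spot_sigma**2)
        )
        spot[~mask] = 0.0
        bg_total = img[mask].sum()
        spot *= signal_fraction / (1.0 - signal_fraction) * bg_total / spot.sum()
        img += spot
    if noise_sd > 0:
        img[mask] += rng.normal(0.0, noise_sd, size=int(mask.sum()))
        img = np.clip(img, 0.0, None)
    return CellImage(intensity=img, roi_mask=mask)


def gen_sensor_image(
    nc_ratio: float = 3.0,
    nucleus_fraction: float = 0.1,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_side: int = 100,
) -> CellImage:
    """Cell with a nuclear/cytoplasmic sensor.

    Cytoplasm at intensity 1, a central nucleus disk (area
    ``nucleus_fraction`` of the ROI) at ``nc_ratio``.  The in-ROI CV grows
    with ``nc_ratio`` above 1, so a time series of falling ``nc_ratio``
    yields a rising MAPK-activity metric.
    """
    if nc_ratio <= 0:
        raise ParameterError("nc_ratio must be > 0")
    if not 0.0 <= nucleus_fraction < 1.0:
        raise ParameterError("nucleus_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    c = (n_side - 1) / 2.0
    roi_r = 0.45 * n_side
    mask = _disk_mask(n_side, (c, c), roi_r)
    img = np.zeros((n_side, n_side))
    img[mask] = 1.0
    if nucleus_fraction > 0:
        nuc = _disk_mask(n_side, (c, c), roi_r * math.sqrt(nucleus_fraction))
        img[nuc & mask] = nc_ratio
    if noise_sd > 0:
        img[mask] += rng.normal(0.0, noise_sd, size=int(mask.sum()))
        img = np.clip(img, 0.0, None)
    return CellImage(intensity=img, roi_mask=mask)


def gen_linescan(
    fold: float = 3.0,
    peak_width: float = 0.5,
    noise_sd: float = 0.0,
    n_points: int = 360,
    seed: int = 0,
    background: float = 0.1,
) -> Linescan:
    """Periodic membrane profile with an exact half-vs-half asymmetry fold.

    The profile is a von-Mises-shaped bump (angular width ``peak_width``
    radians) on a constant base chosen so that the mean over the
    half-contour centred on the peak divided by the mean over the opposite
    half equals ``fold`` exactly at zero noise.  ``fold = 1`` gives a flat
    profile.  Gaussian noise of SD ``noise_sd`` (relative to the bump
    height) is added on top of the stored ``background`` level.
    """
    if fold < 1:
        raise ParameterError("fold must be >= 1")
    if n_points < 8 or n_points % 4:
        raise ParameterError("n_points must be a multiple of 4 and >= 8")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2 * math.pi, n_points, endpoint=False)
    if fold == 1.0:
        values = np.ones(n_points)
    else:
        kappa = 1.0 / peak_width**2
        bump = np.exp(kappa * (np.cos(theta) - 1.0))
        # discrete half-contour means with the same convention asymmetry_fold
        # uses: half window of n/2 samples centred on the peak (index 0)
        centered = np.roll(bump, n_points // 2)
        half = n_points // 4
        sel = slice(n_points // 2 - half, n_points // 2 - half + n_points // 2)
        m_peak = float(centered[sel].mean())
        m_opp = float(np.concatenate([centered[: sel.start], centered[sel.stop:]]).mean())
        if fold > m_peak / m_opp:
            raise ParameterError(
                f"fold {fold} unreachable with peak_width {peak_width}; "
                f"maximum is {m_peak / m_opp:.2f}"
            )
        base = (m_peak - fold * m_opp) / (fold - 1.0)
        values = base + bump
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_points)
    return Linescan(
        positions=theta, intensity=background + values, background=background
    )


def _masked_laplacian(field: NDArray[np.float64], mask: NDArray[np.bool_]) -> NDArray[np.float64]:
    """5-point Laplacian with no-flux (reflecting) walls at the mask edge."""
    lap = np.zeros_like(field)
    for shift, axis in (((1,), 0), ((-1,), 0), ((1,), 1), ((-1,), 1)):
        nb = np.roll(field, shift, axis=axis)
        nb_mask = np.roll(mask, shift, axis=axis)
        contrib = np.where(nb_mask, nb - field, 0.0)
        lap += contrib
    lap[~mask] = 0.0
    return lap


def gen_frap_trace(
    d_true: float,
    w: float = 1.0,
    cell_radius: float = 2.5,
    noise_sd: float = 0.0,
    acquisition_bleach: float = 0.0,
    bleach_depth: float = 0.1,
    seed: int = 0,
    frame_interval: float = 15.0,
    duration: float = 600.0,
    grid_step: float = 0.1,
) -> FRAPTrace:
    """FRAP recovery trace from fine-grid 2D diffusion in a disk.

    Fluorescence diffuses at ``d_true`` (um^2/s) inside a disk cell with
    reflecting walls.  A circular spot of radius ``w`` (offset from the cell
    centre) starts bleached to ``bleach_depth``; the mean signal in the spot
    and over the whole cell is recorded every ``frame_interval`` seconds.
    Acquisition photobleaching multiplies the whole field by
    ``1 - acquisition_bleach`` after each frame; Gaussian noise of SD
    ``noise_sd`` is added to both recorded signals.
    """
    if d_true <= 0:
        raise ParameterError("d_true must be > 0")
    if w >= cell_radius:
        raise ParameterError("bleach spot must be smaller than the cell")
    rng = np.random.default_rng(seed)
    n = int(round(2 * cell_radius / grid_step)) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - (n - 1) / 2) * grid_step
    y = (yy - (n - 1) / 2) * grid_step
    cell = x**2 + y**2 <= cell_radius**2
    offset = -(cell_radius - w) / 2.0  # spot centre halfway to the wall
    spot = (x - offset) ** 2 + y**2 <= w**2
    field = np.where(cell, 1.0, 0.0)
    field[spot & cell] = bleach_depth

    n_frames = int(round(duration / frame_interval)) + 1
    # explicit FTCS stability: D dt / h^2 <= 0.25, with margin
    n_sub = max(1, int(math.ceil(frame_interval * d_true / (0.2 * grid_step**2))))
    dt = frame_interval / n_sub
    alpha = d_true * dt / grid_step**2

    times = np.arange(n_frames) * frame_interval
    bleach_sig = np.empty(n_frames)
    cell_sig = np.empty(n_frames)
    fade = 1.0
    for fr in range(n_frames):
        bleach_sig[fr] = fade * field[spot & cell].mean()
        cell_sig[fr] = fade * field[cell].mean()
        fade *= 1.0 - acquisition_bleach
        if fr < n_frames - 1:
            for _ in range(n_sub):
                field += alpha * _masked_laplacian(field, cell)
    if noise_sd > 0:
        bleach_sig = np.clip(bleach_sig + rng.normal(0, noise_sd, n_frames), 1e-9, None)
        cell_sig = np.clip(cell_sig + rng.normal(0, noise_sd, n_frames), 1e-9, None)
    return FRAPTrace(
        times=times, bleach_signal=bleach_sig, cell_signal=cell_sig, bleach_radius=w
    )


@dataclass(frozen=True)
class MatingFieldTruth:
    """Ground truth recorded alongside a generated mating field."""

    bias_kappa_first: float
    bias_kappa_second: float
    duration_link: bool
    median_indecisive_well: float
    median_indecisive_mis: float


def gen_mating_field(
    n_pairs: int = 50,
    bias_kappa_first: float = 1.0,
    bias_kappa_second: float = 3.0,
    duration_link: bool = False,
    seed: int = 0,
    angle_threshold: float = 60.0,
    median_indecisive: float = 42.0,
    median_indecisive_well: float = 28.0,
    median_indecisive_mis: float = 46.0,
    median_committed: float = 20.0,
) -> tuple[pd.DataFrame, MatingFieldTruth]:
    """Timelines for a field of mating pairs with tunable partner bias.

    Each pair holds a first-born and a (later) second-born cell of opposite
    mating type, 3 um apart.  Initial-cluster angles are drawn from a von
    Mises distribution centred on the partner with stratum-specific
    concentration kappa (kappa = 0 is exactly uniform on [0, 180] degrees —
    the random-orientation null).  Neck directions are independent of the
    partner.  Indecisive-phase durations are lognormal with median 42 min;
    with ``duration_link`` the median depends on whether the cluster formed
    within ``angle_threshold`` of the partner (28 vs 46 min).  Partners
    share a fusion time.
    """
    if bias_kappa_first < 0 or bias_kappa_second < 0:
        raise ParameterError("bias kappas must be >= 0")
    rng = np.random.default_rng(seed)
    pair_sep = 3.0
    cluster_r, neck_r = 1.0, 1.0
    sigma_log = 0.45
    rows = []
    for pair in range(n_pairs):
        base = rng.uniform(0, 2 * math.pi)  # random field orientation
        pos_a = np.array([0.0, 0.0])
        pos_b = pos_a + pair_sep * np.array([math.cos(base), math.sin(base)])
        t_birth_a = float(rng.uniform(0, 5))
        t_birth_b = t_birth_a + float(rng.uniform(2, 10))
        t_p_by_cell = {}
        cells = []
        for cell_pos, partner_pos, order, mtype, t_birth, kappa in (
            (pos_a, pos_b, "first", "a", t_birth_a, bias_kappa_first),
            (pos_b, pos_a, "second", "alpha", t_birth_b, bias_kappa_second),
        ):
            partner_dir = math.atan2(*(partner_pos - cell_pos)[::-1])
            if kappa == 0:
                theta = rng.uniform(0, math.pi)
            else:
                theta = abs(rng.vonmises(0.0, kappa))
            sign = rng.choice([-1.0, 1.0])
            clus_dir = partner_dir + sign * theta
            neck_dir = rng.uniform(0, 2 * math.pi)
            t_ic = t_birth + max(0.5, rng.normal(5.1, 2.8))
            theta_deg = math.degrees(theta)
            if duration_link:
                med = (
                    median_indecisive_well
                    if theta_deg < angle_threshold
                    else median_indecisive_mis
                )
            else:
                med = median_indecisive
            indecisive = float(rng.lognormal(math.log(med), sigma_log))
            t_p = t_ic + indecisive
            cid = f"p{pair}_{order}"
            t_p_by_cell[cid] = t_p
            cells.append(
                {
                    "cell_id": cid,
                    "pair_id": pair,
                    "born_order": order,
                    "mating_type": mtype,
                    "t_birth": t_birth,
                    "t_ic": t_ic,
                    "t_p": t_p,
                    "cell_x": cell_pos[0],
                    "cell_y": cell_pos[1],
                    "cluster_x": cell_pos[0] + cluster_r * math.cos(clus_dir),
                    "cluster_y": cell_pos[1] + cluster_r * math.sin(clus_dir),
                    "partner_x": partner_pos[0],
                    "partner_y": partner_pos[1],
                    "neck_x": cell_pos[0] + neck_r * math.cos(neck_dir),
                    "neck_y": cell_pos[1] + neck_r * math.sin(neck_dir),
                }
            )
        committed = float(rng.lognormal(math.log(median_committed), 0.4))
        t_fusion = max(t_p_by_cell.values()) + committed
        for cell in cells:
            cell["t_fusion"] = t_fusion
            rows.append(cell)
    df = pd.DataFrame(rows)[list(TIMELINE_COLUMNS)]
    truth = MatingFieldTruth(
        bias_kappa_first=bias_kappa_first,
        bias_kappa_second=bias_kappa_second,
        duration_link=duration_link,
        median_indecisive_well=median_indecisive_well if duration_link else median_indecisive,
        median_indecisive_mis=median_indecisive_mis if duration_link else median_indecisive,
    )
    return df, truth
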