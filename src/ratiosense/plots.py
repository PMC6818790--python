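"""Optional plotting helpers (matplotlib); all figures are side outputs.

These mirror the diagnostic views used when developing the metrics: the
steady-state gradient profiles for the two models, and the CV-vs-expression
diagnostic of the MAPK sensor metric on synthetic images.
"""

from __future__ import annotations

import numpy as np

from .image_metrics import coefficient_of_variation
from .steady_state import SteadyStateParams, gradient_profile
from .synthetic import gen_sensor_image


def plot_gradient_profiles(params: SteadyStateParams, ax=None):
    """Ratiometric vs nonratiometric active-G profiles for one (beta, sigma)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for model, style in (("ratiometric", "-"), ("nonratiometric", "--")):
        prof = gradient_profile(params, model)
        ax.plot(prof.positions, prof.g_star, style, label=model)
    ax.set_xlabel("position (um)")
    ax.set_ylabel("active G fraction")
    ax.set_title(f"beta={params.beta}, steepness={params.steepness}")
    ax.legend()
    return ax


def plot_cv_vs_expression(
    nc_ratios=(1.0, 1.5, 2.0, 2.5, 3.0), scales=(0.5, 1.0, 2.0), seed: int = 0, ax=None
):
    """CV of the synthetic nuclear sensor vs overall expression level.

    The CV is scale-invariant, so curves at different expression scales
    should superimpose — the property that makes CV a usable proxy for the
    nuclear-to-cytoplasmic ratio across cells of varying brightness.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for scale in scales:
        cvs = []
        for ratio in nc_ratios:
            img = gen_sensor_image(nc_ratio=ratio, seed=seed)
            img.intensity = img.intensity * scale
            cvs.append(coefficient_of_variation(img))
        ax.plot(nc_ratios, cvs, "o-", label=f"expression x{scale}")
    ax.set_xlabel("nuclear:cytoplasmic ratio")
    ax.set_ylabel("pixel-intensity CV")
    ax.legend()
    return ax
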