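"""Shared fixtures: expensive simulation campaigns reused across tests."""

import numpy as np
import pytest

from ratiosense import SimConfig, calibrate_nonratiometric_rate
from ratiosense.experiments import orientation_sweep

#: reduced study scale used by the simulation-level checks
SIM_SCALE = dict(n_receptors=1000, n_gproteins=250)


@pytest.fixture(scope="session")
def calibrated_rate() -> dict:
    """Nonratiometric k_inact matched to the ratiometric model at 50% occupancy."""
    cfg = SimConfig(**SIM_SCALE, duration=600.0, seed=0)
    return calibrate_nonratiometric_rate(cfg, tolerance=0.02)


@pytest.fixture(scope="session")
def orientation_data(calibrated_rate):
    """Directional-sensing sweep over models and density-gradient orientations.

    16 seeds per condition at 1,000 receptors / 250 G proteins, 900-s runs
    with a 600-s steady-state window.
    """
    conditions = [
        ("ratiometric", "uniform"),
        ("ratiometric", "aligned"),
        ("ratiometric", "opposed"),
        ("ratiometric", "orthogonal"),
        ("nonratiometric", "uniform"),
        ("nonratiometric", "opposed"),
        ("nonratiometric", "orthogonal"),
    ]
    return orientation_sweep(
        conditions,
        n_seeds=16,
        k_inact=calibrated_rate["k_inact"],
        seed_base=1000,
        **SIM_SCALE,
    )
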