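"""Particle simulator: placement, diffusion, reactions, reproducibility."""

import warnings

import numpy as np
import pytest
from scipy import stats

from ratiosense import (
    ConfigurationError,
    GradientSpec,
    ParameterError,
    SimConfig,
    SphereGeometry,
    assign_activity,
    diffuse_step,
    g_vector_angle,
    place_receptors,
    react_step,
    run_simulation,
)
from ratiosense.particles import add_gproteins, _ReceptorIndex

GEOM = SphereGeometry()
AXIS = np.array([0.0, 0.0, 1.0])


class TestPlacement:
    def test_uniform_hemispheres_balanced(self):
        pop = place_receptors(GEOM, 100_000, None, rng=1)
        up = int((pop.receptor_positions @ AXIS > 0).sum())
        # binomial 4-sigma band around n/2
        assert abs(up - 50_000) < 4 * np.sqrt(100_000 * 0.25)

    def test_three_fold_density_gradient(self):
        spec = GradientSpec.density(fold=3.0)
        pop = place_receptors(GEOM, 100_000, spec, rng=2)
        u = pop.receptor_positions @ AXIS / GEOM.radius
        counts, edges = np.histogram(u, bins=20, range=(-1, 1))
        centers = (edges[:-1] + edges[1:]) / 2
        fit = stats.linregress(centers, counts)
        pole_ratio = (fit.intercept + fit.slope) / (fit.intercept - fit.slope)
        assert pole_ratio == pytest.approx(3.0, rel=0.10)

    def test_single_receptor_on_surface(self):
        pop = place_receptors(GEOM, 1, None, rng=3)
        assert np.linalg.norm(pop.receptor_positions[0]) == pytest.approx(GEOM.radius)

    def test_bad_fold_rejected(self):
        with pytest.raises(ParameterError):
            GradientSpec.density(fold=-1.0)


class TestActivity:
    def test_flat_half_activity(self):
        pop = place_receptors(GEOM, 100_000, None, rng=4)
        assign_activity(pop, GradientSpec.activity(lo=0.5, hi=0.5), rng=5)
        assert pop.receptor_active.mean() == pytest.approx(0.5, abs=0.01)

    def test_gradient_polarises_active_fraction(self):
        pop = place_receptors(GEOM, 50_000, None, rng=6)
        assign_activity(pop, GradientSpec.activity(lo=0.40, hi=0.60), rng=7)
        u = pop.receptor_positions @ AXIS
        up_frac = pop.receptor_active[u > 0].mean()
        down_frac = pop.receptor_active[u < 0].mean()
        assert up_frac > down_frac
        assert pop.receptor_active.mean() == pytest.approx(0.5, abs=0.01)

    def test_zero_activity(self):
        pop = place_receptors(GEOM, 1000, None, rng=8)
        assign_activity(pop, GradientSpec.activity(lo=0.0, hi=0.0), rng=9)
        assert pop.receptor_active.sum() == 0


class TestDiffusion:
    def test_zero_d_leaves_positions_untouched(self):
        rng = np.random.default_rng(10)
        pop = place_receptors(GEOM, 100, None, rng=11)
        out = diffuse_step(pop.receptor_positions, 0.0, 0.1, GEOM.radius, rng)
        assert out is pop.receptor_positions

    def test_msd_matches_planar_limit(self):
        # per-step mean squared geodesic displacement = 4 D dt within 5%
        rng = np.random.default_rng(12)
        pos = place_receptors(GEOM, 10_000, None, rng=13).receptor_positions
        new = diffuse_step(pos, 0.002, 0.1, GEOM.radius, rng)
        chord = np.linalg.norm(new - pos, axis=1)
        geo = 2 * GEOM.radius * np.arcsin(chord / (2 * GEOM.radius))
        assert (geo**2).mean() == pytest.approx(4 * 0.002 * 0.1, rel=0.05)

    def test_positions_stay_on_sphere(self):
        rng = np.random.default_rng(14)
        pos = place_receptors(GEOM, 500, None, rng=15).receptor_positions
        for _ in range(200):
            pos = diffuse_step(pos, 0.01, 0.1, GEOM.radius, rng)
        r = np.linalg.norm(pos, axis=1)
        assert np.max(np.abs(r - GEOM.radius)) < 1e-9 * GEOM.radius

    def test_long_run_stationary_distribution_uniform(self):
        # particles started at a pole relax to the uniform distribution on
        # the sphere: KS of cos(theta) against Unif(-1, 1)
        rng = np.random.default_rng(16)
        pos = np.tile([0.0, 0.0, GEOM.radius], (1000, 1))
        for _ in range(10_000):
            pos = diffuse_step(pos, 0.002, 1.0, GEOM.radius, rng)
        u = pos @ AXIS / GEOM.radius
        p = stats.kstest(u, stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 0.01


class TestReactions:
    def _pop(self, n_r=2000, n_g=500, active_frac=0.5, seed=20, g_active=0.0):
        rng = np.random.default_rng(seed)
        pop = place_receptors(GEOM, n_r, None, rng)
        assign_activity(pop, GradientSpec.activity(lo=active_frac, hi=active_frac), rng)
        add_gproteins(pop, n_g, rng, active_fraction=g_active)
        return pop, rng

    def test_no_active_receptors_no_activation(self):
        pop, rng = self._pop(active_frac=0.0)
        cfg = SimConfig(n_receptors=2000, n_gproteins=500, duration=1.0)
        for _ in range(50):
            react_step(pop, cfg, rng)
        assert pop.g_active.sum() == 0

    def test_all_active_receptors_monotone_activation(self):
        pop, rng = self._pop(active_frac=1.0)
        cfg = SimConfig(n_receptors=2000, n_gproteins=500, duration=1.0)
        counts = []
        index = _ReceptorIndex(pop)
        for _ in range(100):
            pop.g_positions = diffuse_step(pop.g_positions, 0.002, 0.1, GEOM.radius, rng)
            react_step(pop, cfg, rng, index)
            counts.append(pop.g_active.sum())
        assert np.all(np.diff(counts) >= 0)

    def test_channel_symmetry_at_half_occupancy(self):
        # at 50% occupancy the activation and inactivation channels have
        # identical kinetics: event counts from a half-active start are
        # statistically equal, independent of the reaction probability
        for p_lambda in (1.0, 0.1):
            pop, rng = self._pop(n_r=5000, n_g=2000, g_active=0.5, seed=21)
            cfg = SimConfig(
                n_receptors=5000, n_gproteins=2000, duration=1.0, p_lambda=p_lambda
            )
            index = _ReceptorIndex(pop)
            gains = losses = 0
            for _ in range(200):
                pop.g_positions = diffuse_step(
                    pop.g_positions, 0.002, 0.1, GEOM.radius, rng
                )
                before = pop.g_active.copy()
                react_step(pop, cfg, rng, index)
                gains += int((~before & pop.g_active).sum())
                losses += int((before & ~pop.g_active).sum())
            total = gains + losses
            assert total > 0
            # two-sided binomial band at ~4 sigma
            assert abs(gains - total / 2) < 4 * np.sqrt(total * 0.25)

    def test_nonratiometric_requires_rate(self):
        with pytest.raises(ConfigurationError):
            SimConfig(mode="nonratiometric")

    def test_flag_only_mutation(self):
        pop, rng = self._pop()
        cfg = SimConfig(n_receptors=2000, n_gproteins=500, duration=1.0)
        r_pos = pop.receptor_positions.copy()
        g_pos = pop.g_positions.copy()
        react_step(pop, cfg, rng)
        assert np.array_equal(pop.receptor_positions, r_pos)
        assert np.array_equal(pop.g_positions, g_pos)
        assert len(pop.g_active) == 500 and len(pop.receptor_active) == 2000


class TestGVectorAngle:
    def test_poles(self):
        up = np.array([[0.0, 0.0, 2.5], [0.0, 0.1, 2.49]])
        assert g_vector_angle(up, AXIS) < 2.0
        assert g_vector_angle(-up, AXIS) > 178.0

    def test_antipodal_pair_undefined(self):
        pts = np.array([[0.0, 0.0, 2.5], [0.0, 0.0, -2.5]])
        assert np.isnan(g_vector_angle(pts, AXIS))

    def test_empty_undefined(self):
        assert np.isnan(g_vector_angle(np.empty((0, 3)), AXIS))


class TestRunSimulation:
    def test_identical_seed_bit_identical_trace(self):
        cfg = SimConfig(n_receptors=500, n_gproteins=100, duration=30.0, seed=42)
        grads = [GradientSpec.activity()]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = run_simulation(cfg, grads, record_interval=5)
            t2 = run_simulation(cfg, grads, record_interval=5)
        assert np.array_equal(t1.active_g_count, t2.active_g_count)
        assert np.array_equal(t1.g_vector, t2.g_vector)

    def test_timestep_warning_emitted(self):
        cfg = SimConfig(n_receptors=100, n_gproteins=10, duration=1.0, seed=1)
        with pytest.warns(UserWarning, match="reactive"):
            run_simulation(cfg, [], record_interval=1)
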