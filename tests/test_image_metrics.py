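"""Clustering parameter, MAPK CV metric and linescan operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratiosense import (
    CellImage,
    Linescan,
    ParameterError,
    asymmetry_fold,
    average_centered_linescans,
    clustering_parameter,
    coefficient_of_variation,
    cv_series,
    mapk_activity,
    max_project,
    normalize_linescan,
)
from ratiosense.image_metrics import CVSeries


def image_from(values: np.ndarray) -> CellImage:
    arr = np.asarray(values, dtype=float)
    side = int(np.sqrt(arr.size))
    arr = arr[: side * side].reshape(side, side)
    return CellImage(intensity=arr, roi_mask=np.ones_like(arr, dtype=bool))


class TestClusteringParameter:
    def test_uniform_spread_is_near_zero(self):
        # empirical CDF equal to the identity -> CP ~ 0
        img = image_from(np.linspace(0, 1, 10000))
        assert clustering_parameter(img).cp < 5e-3

    def test_single_bright_pixel(self):
        vals = np.zeros(10000)
        vals[123] = 1.0
        res = clustering_parameter(image_from(vals))
        assert res.cp == pytest.approx(0.9978, abs=1e-4)
        assert 0.99 <= res.cp <= 1.0

    def test_quarter_max_pixels(self):
        # D(i) = 0.75 on (0,1): CP = 2*int(0.75 - i)di = 0.5
        vals = np.zeros(10000)
        vals[:2500] = 1.0
        assert clustering_parameter(image_from(vals)).cp == pytest.approx(0.5, abs=5e-3)

    def test_half_half_image_is_zero(self):
        # a documented quirk: D = 0.5 everywhere cancels the uniform CDF
        vals = np.zeros(10000)
        vals[:5000] = 1.0
        assert clustering_parameter(image_from(vals)).cp == 0.0

    def test_constant_image_degenerate(self):
        res = clustering_parameter(image_from(np.full(400, 7.0)))
        assert res.cp == 0.0 and res.degenerate

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(min_value=0.1, max_value=100.0),
        b=st.floats(min_value=0.0, max_value=50.0),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_affine_invariance_exact(self, a, b, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(400)
        base = clustering_parameter(image_from(vals)).cp
        scaled = clustering_parameter(image_from(a * vals + b)).cp
        assert scaled == base

    def test_bounded_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            kind = rng.integers(3)
            if kind == 0:
                vals = rng.random(400)
            elif kind == 1:
                vals = np.abs(rng.normal(1.0, 0.3, 400))
            else:
                vals = np.full(400, 0.2)
                vals[rng.integers(0, 400, 10)] = 5.0
            cp = clustering_parameter(image_from(vals)).cp
            assert 0.0 <= cp <= 1.0

    def test_quadratures_agree_closely(self):
        rng = np.random.default_rng(7)
        img = image_from(rng.random(2500))
        mean_cp = clustering_parameter(img, quadrature="mean").cp
        trap_cp = clustering_parameter(img, quadrature="trapezoid").cp
        assert mean_cp == pytest.approx(trap_cp, abs=3e-3)


class TestMapkActivity:
    def test_reference_frame_scores_one(self):
        s = CVSeries(times=np.arange(4.0), cv=np.array([0.8, 0.6, 0.5, 0.4]))
        m = mapk_activity(s)
        assert m[-1] == pytest.approx(1.0)

    def test_doubled_cv_scores_zero(self):
        s = CVSeries(times=np.arange(2.0), cv=np.array([0.8, 0.4]))
        assert mapk_activity(s)[0] == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        frames = [image_from(np.abs(rng.normal(1, 0.4, 400))) for _ in range(5)]
        m1 = mapk_activity(cv_series(frames))
        scaled = [
            CellImage(intensity=f.intensity * 3.7, roi_mask=f.roi_mask) for f in frames
        ]
        m2 = mapk_activity(cv_series(scaled))
        assert np.allclose(m1, m2)

    def test_zero_reference_rejected(self):
        s = CVSeries(times=np.arange(2.0), cv=np.array([0.5, 0.0]))
        with pytest.raises(ParameterError):
            mapk_activity(s)

    def test_max_project(self):
        stack = np.stack([np.zeros((4, 4)), np.eye(4)])
        assert np.array_equal(max_project(stack), np.eye(4))


def make_scan(values, background=0.0):
    n = len(values)
    return Linescan(
        positions=np.linspace(0, 2 * np.pi, n, endpoint=False),
        intensity=np.asarray(values, dtype=float),
        background=background,
    )


class TestLinescans:
    def test_flat_trace_integral_one(self):
        ls = make_scan(np.full(100, 2.0), background=1.0)
        out = normalize_linescan(ls, "integral_one")
        assert np.allclose(out.intensity, 1.0 / (2 * np.pi))

    def test_integral_one_affine_invariance(self):
        rng = np.random.default_rng(5)
        vals = 1.0 + rng.random(120)
        a = normalize_linescan(make_scan(vals, background=0.5))
        b = normalize_linescan(make_scan(2 * vals, background=1.0))
        assert np.allclose(a.intensity, b.intensity)

    def test_percent_max(self):
        out = normalize_linescan(make_scan([1.0, 3.0, 2.0, 1.0] * 25), "percent_max")
        assert out.intensity.max() == pytest.approx(100.0)

    def test_all_background_rejected(self):
        with pytest.raises(ParameterError):
            normalize_linescan(make_scan(np.full(100, 0.3), background=0.3))

    def test_centering_recovers_common_profile(self):
        rng = np.random.default_rng(11)
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        profile = 1.0 + np.exp(2.0 * (np.cos(theta) - 1))
        scans = [
            make_scan(np.roll(profile, rng.integers(0, 120))) for _ in range(6)
        ]
        avg = average_centered_linescans(scans, smoothing=0.0)
        assert np.allclose(avg.mean, np.roll(profile, 60), atol=1e-8)
        assert np.allclose(avg.sd, 0.0, atol=1e-8)
        # with smoothing on, alignment may shift by a sample but the peak
        # stays at the centre
        smoothed = average_centered_linescans(scans, smoothing=0.2)
        assert abs(int(np.argmax(smoothed.mean)) - 60) <= 1

    def test_noise_shows_in_sd_band(self):
        rng = np.random.default_rng(13)
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        profile = 1.0 + 3 * np.exp(4.0 * (np.cos(theta) - 1))
        scans = [
            make_scan(profile + rng.normal(0, 0.05, 120)) for _ in range(40)
        ]
        avg = average_centered_linescans(scans)
        off_peak = np.r_[0:30, 90:120]
        assert np.median(avg.sd[off_peak]) == pytest.approx(0.05, rel=0.5)

    def test_uniform_scans_flagged(self):
        scans = [make_scan(np.ones(60)) for _ in range(3)]
        avg = average_centered_linescans(scans)
        assert avg.tie_flagged


class TestAsymmetryFold:
    def test_flat_profile_is_one(self):
        assert asymmetry_fold(np.ones(100)) == pytest.approx(1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(17)
        profile = 1.0 + np.exp(3 * (np.cos(np.linspace(0, 2 * np.pi, 96, endpoint=False)) - 1))
        base = asymmetry_fold(profile)
        for _ in range(5):
            assert asymmetry_fold(np.roll(profile, rng.integers(96))) == pytest.approx(
                base, rel=1e-12
            )

    def test_fold_at_least_one(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            assert asymmetry_fold(0.1 + rng.random(80)) >= 1.0

    def test_zero_opposite_half_gives_inf(self):
        vals = np.zeros(80)
        vals[40] = 1.0
        assert asymmetry_fold(vals) == np.inf
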