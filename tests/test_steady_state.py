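"""Steady-state G-protein model: closed forms vs the mass-action ODE oracle."""

import numpy as np
import pytest

from ratiosense import (
    ParameterError,
    SteadyStateParams,
    delta_g,
    g_nonratiometric,
    g_ratiometric,
    gradient_profile,
    profile_curvature,
    signal_ratio,
    upgradient_fraction,
)

from _oracles import g_nonratiometric_ode, g_ratiometric_ode

BETAS = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]


class TestGFunctions:
    def test_beta_one_identity(self):
        # at beta = 1 the G-protein gradient equals the receptor gradient
        f = np.linspace(0, 1, 11)
        assert np.allclose(g_ratiometric(f, 1.0), f)

    @pytest.mark.parametrize(
        "f, beta, expected",
        [(0.5, 1.0, 0.5), (0.0, 3.0, 0.0), (0.6, 2.0, 0.42857142857)],
    )
    def test_ratiometric_values(self, f, beta, expected):
        assert g_ratiometric(f, beta) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize(
        "f, beta, expected",
        [(0.5, 1.0, 0.5), (1.0, 4.0, 1.0 / 3.0), (0.25, 2.0, 0.2)],
    )
    def test_nonratiometric_values(self, f, beta, expected):
        assert g_nonratiometric(f, beta) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("beta", BETAS)
    def test_agreement_with_ode_oracle(self, beta):
        for f in np.linspace(0.0, 1.0, 9):
            assert g_ratiometric(f, beta) == pytest.approx(
                g_ratiometric_ode(f, beta), abs=1e-8
            )
            assert g_nonratiometric(f, beta) == pytest.approx(
                g_nonratiometric_ode(f, beta), abs=1e-8
            )

    def test_models_match_at_midpoint(self):
        for beta in BETAS:
            assert g_ratiometric(0.5, beta) == pytest.approx(
                g_nonratiometric(0.5, beta), abs=1e-12
            )

    def test_monotone_in_f_and_beta(self):
        f = np.linspace(0.01, 0.99, 50)
        for beta in BETAS:
            assert np.all(np.diff(g_ratiometric(f, beta)) > 0)
        # raising beta lowers active G pointwise
        for b_lo, b_hi in zip(BETAS[:-1], BETAS[1:]):
            assert np.all(g_ratiometric(f, b_hi) < g_ratiometric(f, b_lo))
            assert np.all(g_nonratiometric(f, b_hi) < g_nonratiometric(f, b_lo))

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            g_ratiometric(0.5, -1.0)
        with pytest.raises(ParameterError):
            g_ratiometric(1.5, 1.0)
        with pytest.raises(ParameterError):
            g_nonratiometric(-0.1, 1.0)


class TestDeltaGAndSignalRatio:
    def test_flat_gradient_gives_zero(self):
        p = SteadyStateParams(beta=3.0, steepness=0.0)
        assert delta_g(p, "ratiometric") == 0.0
        assert delta_g(p, "nonratiometric") == 0.0

    def test_full_steepness_endpoints(self):
        p = SteadyStateParams(beta=4.0, steepness=1.0)
        assert delta_g(p, "ratiometric") == pytest.approx(1.0)
        assert delta_g(p, "nonratiometric") == pytest.approx(1.0 / 3.0, abs=1e-10)

    @pytest.mark.parametrize("beta, expected", [(4.0, 3.0), (2.0, 2.0)])
    def test_sr_at_full_steepness(self, beta, expected):
        p = SteadyStateParams(beta=beta, steepness=1.0)
        assert signal_ratio(p) == pytest.approx(expected, rel=1e-10)
        # cross-check against the ODE oracle at the endpoints
        num = g_ratiometric_ode(1.0, beta) - g_ratiometric_ode(0.0, beta)
        den = g_nonratiometric_ode(1.0, beta) - g_nonratiometric_ode(0.0, beta)
        assert signal_ratio(p) == pytest.approx(num / den, rel=1e-6)

    def test_sr_shallow_limit_is_two(self):
        for beta in [0.5, 1.0, 2.0, 5.0]:
            sr = signal_ratio(SteadyStateParams(beta=beta, steepness=1e-3))
            assert sr == pytest.approx(2.0, abs=5e-3)
            # Richardson consistency: closer still at sigma = 1e-4
            sr4 = signal_ratio(SteadyStateParams(beta=beta, steepness=1e-4))
            # (absolute floor covers beta = 1 where SR is exactly 2)
            assert abs(sr4 - 2.0) < abs(sr - 2.0) + 1e-9

    def test_ratiometric_never_loses(self):
        for beta in BETAS:
            for sigma in np.linspace(0.05, 1.0, 10):
                assert signal_ratio(SteadyStateParams(beta=beta, steepness=sigma)) >= 1.0

    def test_sr_undefined_at_zero_steepness(self):
        with pytest.raises(ParameterError):
            signal_ratio(SteadyStateParams(beta=1.0, steepness=0.0))


class TestCurvature:
    @pytest.mark.parametrize(
        "model, beta, expected",
        [
            ("ratiometric", 4.0, "convex"),
            ("ratiometric", 1.0, "linear"),
            ("ratiometric", 0.5, "concave"),
            ("nonratiometric", 0.5, "concave"),
            ("nonratiometric", 4.0, "concave"),
        ],
    )
    def test_regimes(self, model, beta, expected):
        p = SteadyStateParams(beta=beta, steepness=0.8)
        assert profile_curvature(gradient_profile(p, model)) == expected

    def test_indeterminate_for_mixed_signs(self):
        from ratiosense.steady_state import GProfile

        wiggly = GProfile(
            positions=np.linspace(0, 5, 7),
            g_star=np.array([0.0, 0.3, 0.2, 0.5, 0.4, 0.7, 0.8]),
            model="ratiometric",
        )
        assert profile_curvature(wiggly) == "indeterminate"

    def test_convex_profile_concentrates_g_up_gradient(self):
        # beta > 1: the ratiometric model puts a larger share of active G
        # in the up-gradient fifth of the cell
        p = SteadyStateParams(beta=4.0, steepness=0.8)
        assert upgradient_fraction(p, "ratiometric") > upgradient_fraction(
            p, "nonratiometric"
        )


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta": 0.0, "steepness": 0.5},
            {"beta": 1.0, "steepness": 1.2},
            {"beta": 1.0, "steepness": 0.5, "midpoint_occupancy": 0.0},
            {"beta": 1.0, "steepness": 1.0, "midpoint_occupancy": 0.8},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SteadyStateParams(**kwargs)

    def test_profile_values_bounded(self):
        for beta in BETAS:
            prof = gradient_profile(
                SteadyStateParams(beta=beta, steepness=1.0), "ratiometric"
            )
            assert np.all(prof.g_star >= 0) and np.all(prof.g_star <= 1)
            assert np.all(np.diff(prof.g_star) >= 0)
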