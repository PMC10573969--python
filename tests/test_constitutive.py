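"""Closed-form constitutive relations: examples, identities, and an
independent ODE oracle for the SLS creep compliance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from pdlvisco import (
    ReducedCreepParameters,
    SLSParameters,
    SchaperyParameters,
    StepLoad,
    creep_compliance,
    full_from_reduced,
    g1_from_strains,
    kelvin_voigt_from_sls,
    reduced_from_full,
    strain_response,
    stress_from_load,
)
from pdlvisco.constitutive import (
    DegenerateInputError,
    DomainError,
    ValidationError,
)

moduli = st.floats(0.05, 50.0, allow_nan=False)
viscosities = st.floats(0.1, 1000.0, allow_nan=False)


def sls_ode_compliance(sls: SLSParameters, t: np.ndarray) -> np.ndarray:
    """Independent oracle: integrate the spring-parallel-Maxwell ODE.

    Under unit step stress, eliminating the branch stresses gives
    deps/dt = Em (1 - Etf*eps) / (eta (Em + Etf)), eps(0) = 1/(Etf+Em);
    the compliance is eps(t) itself.
    """
    Etf, Em, eta = sls.Etf, sls.Em, sls.eta

    def rhs(_, y):
        return [Em * (1.0 - Etf * y[0]) / (eta * (Em + Etf))]

    sol = solve_ivp(
        rhs, (0.0, float(t[-1])), [1.0 / (Etf + Em)], t_eval=t,
        rtol=1e-12, atol=1e-14, method="LSODA",
    )
    return sol.y[0]


class TestCreepCompliance:
    @pytest.mark.parametrize(
        "sls, t, expected",
        [
            (SLSParameters(1, 1, 1), 0.0, 0.5),  # parallel springs at t=0
            (SLSParameters(2, 3, 5), 1e12, 0.5),  # equilibrium 1/Etf
            (SLSParameters(1, 1, 1), 1.0, 1 - 0.5 * np.exp(-0.5)),
        ],
    )
    def test_closed_form_values(self, sls, t, expected):
        assert creep_compliance(sls, t) == pytest.approx(expected, rel=1e-12)

    def test_matches_ode_oracle_on_random_parameters(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 300.0, 40)
        for _ in range(25):
            sls = SLSParameters(
                Etf=rng.uniform(0.1, 20.0),
                Em=rng.uniform(0.1, 20.0),
                eta=rng.uniform(1.0, 500.0),
            )
            d_closed = creep_compliance(sls, t)
            d_ode = sls_ode_compliance(sls, t)
            assert np.allclose(d_closed, d_ode, rtol=1e-8, atol=0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(Etf=moduli, Em=moduli, eta=viscosities)
    def test_monotone_nondecreasing_and_bounded(self, Etf, Em, eta):
        sls = SLSParameters(Etf, Em, eta)
        t = np.linspace(0.0, 10.0 * sls.tau1, 200)
        d = creep_compliance(sls, t)
        assert np.all(np.diff(d) >= 0)
        assert d[0] == pytest.approx(1.0 / (Etf + Em), rel=1e-12)
        assert np.all(d <= 1.0 / Etf + 1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            creep_compliance(SLSParameters(1, 1, 1), -0.1)

    @pytest.mark.parametrize("bad", [dict(Etf=0), dict(Em=-1), dict(eta=np.nan)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(Etf=1.0, Em=1.0, eta=1.0) | bad
        with pytest.raises(ValidationError):
            SLSParameters(**kwargs)


class TestKelvinVoigtMapping:
    def test_unit_case(self):
        kv = kelvin_voigt_from_sls(SLSParameters(1, 1, 1))
        assert kv.D0p == pytest.approx(1.5)
        assert kv.D1p == pytest.approx(-0.5)
        assert kv.tau1 == pytest.approx(2.0)

    def test_vanishing_matrix_limit(self):
        kv = kelvin_voigt_from_sls(SLSParameters(2.0, 1e-9, 1.0))
        assert kv.D0p == pytest.approx(0.5, rel=1e-6)
        assert kv.D1p == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(Etf=moduli, Em=moduli, eta=viscosities)
    def test_equilibrium_identity_and_timescale(self, Etf, Em, eta):
        sls = SLSParameters(Etf, Em, eta)
        kv = kelvin_voigt_from_sls(sls)
        # D0' + D1' = 1/Etf is an exact algebraic identity
        assert kv.D0p + kv.D1p == pytest.approx(1.0 / Etf, rel=1e-12)
        assert kv.tau1 == pytest.approx(sls.tau1, rel=1e-14)


class TestStrainResponse:
    def test_zero_stress_gives_zero_strain(self, hold_grid):
        sch = SchaperyParameters(g0=0.7, g1=1.0, g2=-0.3)
        eps = strain_response(sch, SLSParameters(2, 3, 5), StepLoad(0.0), hold_grid)
        assert np.all(eps == 0.0)

    def test_published_neck_column_endpoints(self):
        """Instantaneous and asymptotic strain for the first neck sample."""
        sch = SchaperyParameters(g0=0.0049, g1=1.0, g2=-0.0096)
        sls = SLSParameters(1.0, 1.0, 260.8893)
        load = StepLoad(1.0)
        assert strain_response(sch, sls, load, 0.0) == pytest.approx(0.00735)
        assert strain_response(sch, sls, load, 1e9) == pytest.approx(0.01215)

    def test_unit_factors_reduce_to_kv_compliance_form(self, hold_grid):
        """g0 = g1 = 1, g2 = -1: eps = D0' + |D1'|(1 - e^(-t/tau)).

        The long-time value (3Em+Etf)/(Etf(Etf+Em)) exceeds the linear SLS
        equilibrium 1/Etf — a property of the strain law's sign structure.
        """
        sls = SLSParameters(2.0, 3.0, 7.0)
        kv = kelvin_voigt_from_sls(sls)
        sch = SchaperyParameters(g0=1.0, g1=1.0, g2=-1.0)
        eps = strain_response(sch, sls, StepLoad(1.0), hold_grid)
        expected = kv.D0p + abs(kv.D1p) * (1 - np.exp(-hold_grid / kv.tau1))
        assert np.allclose(eps, expected, rtol=1e-14)
        eps_inf = strain_response(sch, sls, StepLoad(1.0), 1e12)
        assert eps_inf == pytest.approx(
            (3 * sls.Em + sls.Etf) / (sls.Etf * (sls.Etf + sls.Em))
        )
        assert eps_inf > 1.0 / sls.Etf

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        g0=st.floats(0.001, 0.02), g2=st.floats(-0.03, -0.001),
        eta=st.floats(50.0, 500.0), sigma0=st.floats(0.1, 10.0),
    )
    def test_creep_regime_is_nondecreasing_and_bounded(self, g0, g2, eta, sigma0):
        sch = SchaperyParameters(g0=g0, g1=1.0, g2=g2)
        sls = SLSParameters(1.0, 1.0, eta)
        load = StepLoad(sigma0)
        t = np.linspace(0.0, 1000.0, 300)
        eps = strain_response(sch, sls, load, t)
        kv = kelvin_voigt_from_sls(sls)
        assert np.all(np.diff(eps) >= 0)
        bound = g0 * kv.D0p * sigma0 + 1.0 * abs(g2) * abs(kv.D1p) * sigma0
        assert np.all(eps <= bound + 1e-15)


class TestReducedParameterization:
    def test_forward_map_example(self):
        red = reduced_from_full(
            SchaperyParameters(g0=1.0, g1=1.0, g2=-1.0),
            SLSParameters(1.0, 1.0, 2.0),
            StepLoad(1.0),
        )
        assert (red.A, red.B, red.tau) == pytest.approx((1.5, 0.5, 4.0))

    def test_g2_zero_means_flat_hold(self, hold_grid):
        red = reduced_from_full(
            SchaperyParameters(g0=0.01, g1=1.0, g2=0.0),
            SLSParameters(1.0, 1.0, 100.0),
            StepLoad(1.0),
        )
        assert red.B == 0.0
        assert np.ptp(red.strain(hold_grid)) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        g0=st.floats(1e-4, 1.0), g2=st.floats(-1.0, -1e-4),
        eta=st.floats(0.5, 500.0),
    )
    def test_round_trip_is_identity(self, g0, g2, eta):
        sch = SchaperyParameters(g0=g0, g1=1.0, g2=g2)
        sls = SLSParameters(1.0, 1.0, eta)
        red = reduced_from_full(sch, sls, StepLoad(1.0))
        sch2, sls2 = full_from_reduced(red, Etf=1.0, Em=1.0, sigma0=1.0, g1=1.0)
        assert sch2.g0 == pytest.approx(g0, rel=1e-10)
        assert sch2.g2 == pytest.approx(g2, rel=1e-10)
        assert sls2.eta == pytest.approx(eta, rel=1e-10)

    def test_reduced_matches_strain_response(self, hold_grid):
        sch = SchaperyParameters(g0=0.0081, g1=1.0, g2=-0.0124)
        sls = SLSParameters(1.0, 1.0, 370.6347)
        load = StepLoad(1.0)
        red = reduced_from_full(sch, sls, load)
        assert np.allclose(
            red.strain(hold_grid), strain_response(sch, sls, load, hold_grid),
            rtol=1e-14,
        )

    def test_g1_zero_inversion_rejected(self):
        red = ReducedCreepParameters(A=1.0, B=0.5, tau=10.0)
        with pytest.raises(DegenerateInputError):
            full_from_reduced(red, Etf=1.0, Em=1.0, sigma0=1.0, g1=0.0)


class TestG1FromStrains:
    @pytest.mark.parametrize(
        "args, expected",
        [
            # full rebound (eps_b0 == eps_r0) -> g1 = 1
            (dict(delta_eps_c=0.01, eps_p=0.0, eps_b0=0.005, eps_r0=0.005), 1.0),
            (dict(delta_eps_c=0.01, eps_p=0.0, eps_b0=0.005, eps_r0=0.0), 2.0),
            (dict(delta_eps_c=0.01, eps_p=0.01, eps_b0=0.0, eps_r0=0.005), 0.0),
        ],
    )
    def test_examples(self, args, expected):
        assert g1_from_strains(**args) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DegenerateInputError):
            g1_from_strains(0.01, 0.0, 0.01, 0.0)


class TestStressFromLoad:
    def test_flat_punch_peak_stress(self):
        """3 mN over the pi R^2 face of a 100 um punch: ~95.5 kPa."""
        S = np.pi * 0.1**2
        assert stress_from_load(3.0, S) == pytest.approx(95.493, rel=1e-4)

    @pytest.mark.parametrize("F, S, expected", [(0.0, 1.0, 0.0), (1.0, 1.0, 1.0)])
    def test_trivial_cases(self, F, S, expected):
        assert stress_from_load(F, S) == expected

    def test_invalid_area_rejected(self):
        with pytest.raises(ValidationError):
            stress_from_load(1.0, 0.0)
        with pytest.raises(ValidationError):
            stress_from_load(-1.0, 1.0)
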