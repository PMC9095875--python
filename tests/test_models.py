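"""Prediction functions: reference values, limiting cases, structural
properties and convention invariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sccosol as s
from sccosol.models import (
    STUDY_MODELS,
    predict_alwi_garlapati,
    predict_bartle,
    predict_chrastil,
    predict_mt,
    predict_new_model,
    predict_r_chrastil,
    predict_reddy_garlapati,
    predict_sodeifian,
)


class TestFugacityRatio:
    def test_unity_at_melting_point(self):
        for dHm in (None, 25000.0):
            for variant in ("printed", "textual"):
                assert s.fugacity_ratio(
                    412.0, 412.0, dHm=dHm, dCp=123.0, melting_term=variant
                ) == pytest.approx(1.0)

    def test_substitution_variants(self):
        # exp(6.54 (1 - 308/412)) and exp(6.54 (1 - 412/308))
        assert s.fugacity_ratio(308.0, 412.0, melting_term="printed") == pytest.approx(
            math.exp(6.54 * (1 - 308 / 412)), rel=1e-12
        )
        assert s.fugacity_ratio(308.0, 412.0, melting_term="printed") == pytest.approx(
            5.212, rel=1e-3
        )
        assert s.fugacity_ratio(308.0, 412.0, melting_term="textual") == pytest.approx(
            0.1099, rel=1e-3
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            s.fugacity_ratio(-1.0, 412.0)
        with pytest.raises(ValueError):
            s.fugacity_ratio(308.0, 412.0, melting_term="bogus")


class TestGammaInfinity:
    def test_symmetry_gives_unity(self):
        # a11 = a22 = a and v2*rho1 = 1 makes the exponent vanish
        assert s.gamma_infinity(308.0, 1 / 2.8202e-4, 2.8202e-4, 5.0, 5.0) == (
            pytest.approx(1.0)
        )

    def test_zero_interactions(self):
        assert s.gamma_infinity(308.0, 769.0, 2.8202e-4, 0.0, 0.0) == 1.0

    def test_reference_evaluation(self):
        # direct high-precision arithmetic of the exponent
        T, rho, v2 = 308.0, 769.0, 2.8202e-4
        a11, a22 = 1.0939e6, 1.3423e3
        sprod = v2 * rho
        expo = (a22 + a11 * sprod - 2 * math.sqrt(a11 * a22) * math.sqrt(sprod)) / (
            8.314 * T
        )
        assert s.gamma_infinity(T, rho, v2, a11, a22) == pytest.approx(
            math.exp(expo), rel=1e-12
        )

    def test_negative_interaction_rejected(self):
        with pytest.raises(ValueError):
            s.gamma_infinity(308.0, 769.0, 2.8202e-4, -1.0, 5.0)

    @given(
        a11=st.floats(0.0, 1e7),
        a22=st.floats(0.0, 1e6),
        rho=st.floats(100.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive(self, a11, a22, rho):
        assert s.gamma_infinity(308.0, rho, 2.8202e-4, a11, a22) > 0


class TestPredictors:
    def test_new_model_unity_at_tm_with_no_interactions(self, constants):
        c = s.SubstanceConstants(solute_melting_temperature=412.0)
        y = predict_new_model(412.0, 12.0, 769.0, (0.0, 0.0, 0.0), c)
        assert y == pytest.approx(1.0)

    def test_new_model_composes_components(self, constants):
        y = predict_new_model(308.0, 12.0, 769.0, (0.0, 0.0, 0.0), constants)
        assert y == pytest.approx(s.fugacity_ratio(308.0, 412.0), rel=1e-12)

    def test_alwi_zero_params(self, constants):
        Tr = 308.0 / constants.solvent_Tc
        rr = 769.0 / constants.solvent_rhoc
        y = predict_alwi_garlapati(308.0, 12.0, 769.0, (0.0, 0.0, 0.0), constants)
        assert y == pytest.approx(1.0 / (rr * Tr), rel=1e-12)

    def test_alwi_cancelling_exponent(self, constants):
        y = predict_alwi_garlapati(
            constants.solvent_Tc, 12.0, constants.solvent_rhoc, (3.0, -3.0, 0.0),
            constants,
        )
        assert y == pytest.approx(1.0, rel=1e-12)

    def test_sodeifian_zero_params(self, constants):
        assert predict_sodeifian(308.0, 12.0, 769.0, np.zeros(6), constants) == 1.0

    def test_sodeifian_reference(self, constants):
        th = (40.0, 0.9, -2.5, 0.003, -0.03, -1800.0)
        T, P, rho = 308.0, 12.0, 769.0
        expected = math.exp(
            th[0]
            + th[1] * P**2 / T
            + th[2] * math.log(rho * T)
            + th[3] * rho * math.log(rho)
            + th[4] * P * math.log(T)
            + th[5] * math.log(rho) / T
        )
        assert predict_sodeifian(T, P, rho, th, constants) == pytest.approx(
            expected, rel=1e-12
        )

    def test_reddy_structure(self, constants):
        Tr = 308.0 / constants.solvent_Tc
        assert predict_reddy_garlapati(
            308.0, 12.0, 769.0, (1, 0, 0, 0, 0, 0), constants
        ) == pytest.approx(Tr**2, rel=1e-12)
        assert predict_reddy_garlapati(308.0, 12.0, 769.0, np.zeros(6), constants) == 0

    def test_chrastil_half_saturation(self, constants):
        # kappa = 1 and E0 = E1 = 0 gives x = 1, y2 = 1/2
        assert predict_chrastil(308.0, 12.0, 769.0, (1.0, 0.0, 0.0), constants) == (
            pytest.approx(0.5)
        )

    def test_chrastil_vanishing_limit(self, constants):
        assert predict_chrastil(308.0, 12.0, 769.0, (7.0, -200.0, -7000.0), constants) < 1e-50

    def test_chrastil_bounded(self, constants):
        y = predict_chrastil(308.0, 12.0, 769.0, (7.0, -28.0, -7000.0), constants)
        assert 0 < y < 1

    def test_r_chrastil_identity(self, constants):
        assert predict_r_chrastil(
            308.0, 12.0, 769.0, (1.0, 0.0, 0.0), constants
        ) == pytest.approx(1.0)

    def test_r_chrastil_fugacity_power_law(self, constants):
        # scaling f-standard by c multiplies y2 by c^(1-kappa')
        th = (6.9, -40.0, -4800.0)
        c = 3.7
        y1 = predict_r_chrastil(308.0, 12.0, 769.0, th, constants)
        scaled = s.SubstanceConstants(rchrastil_f0=c * constants.rchrastil_f0)
        y2 = predict_r_chrastil(308.0, 12.0, 769.0, th, scaled)
        assert y2 / y1 == pytest.approx(c ** (1 - th[0]), rel=1e-10)

    def test_bartle_reference_state(self, constants):
        y = predict_bartle(
            308.0, 12.0, constants.bartle_rhoref, (0.0, 0.0, 0.0), constants
        )
        assert y == pytest.approx(constants.bartle_Pref / 12.0, rel=1e-12)

    def test_bartle_density_independent_when_G2_zero(self, constants):
        th = (20.0, -9000.0, 0.0)
        y1 = predict_bartle(308.0, 12.0, 500.0, th, constants)
        y2 = predict_bartle(308.0, 12.0, 900.0, th, constants)
        assert y1 == y2

    def test_mt_inverse_pressure(self, constants):
        assert predict_mt(308.0, 4.0, 769.0, (0.0, 0.0, 0.0), constants) == (
            pytest.approx(0.25)
        )

    def test_mt_monotone_in_density(self, constants):
        th = (-14000.0, 4.3, 25.0)
        rhos = np.array([400.0, 600.0, 800.0])
        y = predict_mt(308.0, 12.0, rhos, th, constants)
        assert np.all(np.diff(y) > 0)


class TestRegistry:
    def test_study_models_present(self):
        assert len(STUDY_MODELS) == 8
        for mid in STUDY_MODELS:
            s.get_model(mid)

    @pytest.mark.parametrize(
        "mid,q",
        [
            ("new_model", 3), ("alwi_garlapati", 3), ("sodeifian", 6),
            ("reddy_garlapati", 6), ("chrastil", 3), ("r_chrastil", 3),
            ("bartle", 3), ("mt", 3),
        ],
    )
    def test_parameter_counts(self, mid, q):
        assert s.get_model(mid).parameter_count == q

    def test_unknown_model(self):
        with pytest.raises(KeyError):
            s.get_model("cubic_eos")

    def test_parameter_set_length_checked(self):
        with pytest.raises(ValueError):
            s.ParameterSet("chrastil", (1.0, 2.0))

    def test_wrong_theta_length_raises(self, constants):
        with pytest.raises(ValueError):
            s.get_model("bartle")(308.0, 12.0, 769.0, np.zeros(4), constants)

    def test_finite_positive_on_study_grid(self, table2, constants):
        # fitted-region parameter values keep every model positive and finite
        thetas = {
            "new_model": (300.0, 2.0e4, 5.8e4),
            "alwi_garlapati": (2.0, -20.0, 3.6),
            "sodeifian": (40.0, 0.9, -2.5, 0.003, -0.03, -1800.0),
            "reddy_garlapati": (7e-6, -6e-5, 3e-5, -3e-6, 6e-5, -3e-5),
            "chrastil": (7.4, -33.0, -6800.0),
            "r_chrastil": (7.4, -37.0, -4700.0),
            "bartle": (21.0, -9100.0, 0.0125),
            "mt": (-13900.0, 4.2, 24.6),
        }
        T, P, rho, _ = table2.arrays()
        for mid, th in thetas.items():
            y = np.asarray(s.get_model(mid)(T, P, rho, np.array(th), constants))
            assert np.all(np.isfinite(y))
            if mid != "reddy_garlapati":  # polynomial exempt by construction
                assert np.all(y > 0), mid


class TestConventionInvariance:
    """Rescaling a model's convention constants and compensating its
    parameters analytically leaves predictions unchanged."""

    def test_alwi_critical_constant_rescaling(self, table2, constants):
        T, P, rho, _ = table2.arrays()
        th = np.array([2.0, -20.0, 3.6])
        y1 = predict_alwi_garlapati(T, P, rho, th, constants)
        c2 = s.SubstanceConstants(solvent_rhoc=2 * constants.solvent_rhoc)
        # rho_r halves: A2' = 2 A2 and A0' = A0 - ln 2 compensate
        th2 = np.array([th[0] - math.log(2.0), th[1], 2 * th[2]])
        y2 = predict_alwi_garlapati(T, P, rho, th2, c2)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)

    def test_bartle_reference_rescaling(self, table2, constants):
        T, P, rho, _ = table2.arrays()
        th = np.array([21.0, -9100.0, 0.0125])
        y1 = predict_bartle(T, P, rho, th, constants)
        c2 = s.SubstanceConstants(bartle_Pref=1.0, bartle_rhoref=600.0)
        th2 = np.array(
            [th[0] - math.log(1.0 / 0.1) + th[2] * (600.0 - 700.0), th[1], th[2]]
        )
        y2 = predict_bartle(T, P, rho, th2, c2)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)

    def test_chrastil_density_unit_rescaling(self, table2, constants):
        T, P, rho, _ = table2.arrays()
        th = np.array([7.4, -33.0, -6800.0])
        y1 = predict_chrastil(T, P, rho, th, constants)
        # density in g/cm3 = rho/1000: E0' = E0 + (kappa-1) ln 1000
        th2 = np.array([th[0], th[1] + (th[0] - 1) * math.log(1000.0), th[2]])
        y2 = predict_chrastil(T, P, rho / 1000.0, th2, constants)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)

    def test_mt_pressure_unit_rescaling(self, table2, constants):
        T, P, rho, _ = table2.arrays()
        th = np.array([-13900.0, 4.2, 24.6])
        y1 = predict_mt(T, P, rho, th, constants)
        # P in bar = 10 P_MPa: H2' = H2 - ln 10 ... and the leading 1/P
        # gains a factor 10, cancelling exactly
        th2 = np.array([th[0], th[1], th[2] + math.log(10.0)])
        y2 = predict_mt(T, 10.0 * P, rho, th2, constants)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)
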