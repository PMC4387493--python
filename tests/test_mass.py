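"""Calibration regression, prediction intervals, limb equations, armour, DME."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hullmass.errors import DomainError, InsufficientDataError, RegistryError
from hullmass.mass import (
    ArmourSpec,
    CalibrationDataset,
    CalibrationFit,
    LimbEquation,
    MassEstimate,
    SpecimenMeasurements,
    add_components,
    dme_scale,
    fit_power_law,
    get_equation,
    limb_mass,
    load_equation_registry,
    predict_mass,
)
from hullmass.reference import (
    ARMOUR_KG,
    PUBLISHED_TOTALS,
    fixture_calibration_fit,
    published_estimates,
)


def power_law_data(a, b, volumes):
    volumes = np.asarray(volumes, float)
    return CalibrationDataset(
        taxa=[f"t{i}" for i in range(len(volumes))],
        volumes_m3=volumes,
        masses_kg=a * volumes**b,
    )


class TestFitPowerLaw:
    def test_noise_free_exact_recovery(self):
        data = power_law_data(2.5, 0.9, np.logspace(-2, 1, 10))
        fit = fit_power_law(data)
        assert fit.slope == pytest.approx(0.9, abs=1e-10)
        assert fit.intercept == pytest.approx(math.log10(2.5), abs=1e-10)
        assert fit.resid_se == pytest.approx(0.0, abs=1e-10)
        # reproduces calibration points exactly
        for v, m in zip(data.volumes_m3, data.masses_kg):
            assert predict_mass(fit, v).mean == pytest.approx(m, rel=1e-9)

    def test_constant_mass_gives_zero_slope(self):
        data = CalibrationDataset(
            taxa=list("abcd"), volumes_m3=[0.1, 1.0, 5.0, 9.0],
            masses_kg=[100.0] * 4,
        )
        assert fit_power_law(data).slope == pytest.approx(0.0, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(InsufficientDataError):
            fit_power_law(power_law_data(1.0, 1.0, [1.0, 2.0]))
        with pytest.raises(DomainError):
            CalibrationDataset(taxa=["a", "b", "c"], volumes_m3=[1, -1, 2],
                               masses_kg=[1, 1, 1])
        with pytest.raises(InsufficientDataError, match="identical"):
            fit_power_law(CalibrationDataset(
                taxa=list("abc"), volumes_m3=[2.0, 2.0, 2.0],
                masses_kg=[1.0, 2.0, 3.0]))

    def test_two_point_fixture_matches_closed_form(self):
        """The packaged fixture fit equals the hand-derived closed form
        through (1.2800, 1526) and (3.3781, 3711)."""
        fit = fixture_calibration_fit()
        b_expected = math.log10(3711 / 1526) / math.log10(3.3781 / 1.2800)
        a_expected = 1526 / 1.2800**b_expected
        assert fit.b == pytest.approx(b_expected, abs=1e-12)
        assert fit.a == pytest.approx(a_expected, rel=1e-12)
        assert round(fit.b, 3) == 0.916
        assert 1.21e3 < fit.a < 1.23e3


class TestPredictMass:
    def test_zero_residual_se_degenerates(self):
        fit = fixture_calibration_fit()
        est = predict_mass(fit, 2.0)
        assert est.lower == est.mean == est.upper

    def test_fixture_reproduces_published_anchors(self):
        """Predictions at the pref/ce totals return the published hull-derived
        masses (mean minus armour) by construction of the fixture."""
        fit = fixture_calibration_fit()
        assert predict_mass(fit, PUBLISHED_TOTALS["pref"]).mean == pytest.approx(
            1560 - ARMOUR_KG, abs=1e-6)
        assert predict_mass(fit, PUBLISHED_TOTALS["ce"]).mean == pytest.approx(
            3745 - ARMOUR_KG, abs=1e-6)

    def test_monotone_in_volume(self):
        fit = fixture_calibration_fit()
        vols = np.linspace(0.5, 5.0, 20)
        means = [predict_mass(fit, v).mean for v in vols]
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_back_transform_consistency(self):
        """log10(mean) is exactly the linear predictor (no smearing)."""
        rng = np.random.default_rng(17)
        data = power_law_data(1200, 0.92, np.logspace(-2, 1, 15))
        noisy = CalibrationDataset(
            taxa=data.taxa, volumes_m3=data.volumes_m3,
            masses_kg=data.masses_kg * 10 ** rng.normal(0, 0.1, 15))
        fit = fit_power_law(noisy)
        x0 = math.log10(2.345)
        assert math.log10(predict_mass(fit, 2.345).mean) == pytest.approx(
            fit.intercept + fit.slope * x0, abs=1e-12)

    def test_interval_asymmetric_after_back_transform(self):
        rng = np.random.default_rng(18)
        data = power_law_data(1200, 0.92, np.logspace(-2, 1, 15))
        noisy = CalibrationDataset(
            taxa=data.taxa, volumes_m3=data.volumes_m3,
            masses_kg=data.masses_kg * 10 ** rng.normal(0, 0.1, 15))
        est = predict_mass(fit_power_law(noisy), 1.5)
        assert est.lower < est.mean < est.upper
        assert (est.upper - est.mean) > (est.mean - est.lower)

    def test_domain_errors(self):
        fit = fixture_calibration_fit()
        with pytest.raises(DomainError):
            predict_mass(fit, -1.0)
        with pytest.raises(DomainError):
            predict_mass(fit, 1.0, level=1.5)


class TestArmour:
    def test_published_shift(self):
        """(1526, 1048-2222) + 34 kg of armour restores the published
        (1560, 1082-2256)."""
        est = MassEstimate(mean=1526, lower=1048, upper=2222,
                           components=[("hull-derived", 1526)])
        shifted = add_components(est, ArmourSpec(total_kg=34))
        assert (shifted.mean, shifted.lower, shifted.upper) == (1560, 1082, 2256)
        assert ("dermal armour", 34) in shifted.components

    def test_zero_armour_is_identity(self):
        est = MassEstimate(mean=100, lower=80, upper=130)
        shifted = add_components(est, ArmourSpec(total_kg=0.0))
        assert (shifted.mean, shifted.lower, shifted.upper) == (100, 80, 130)

    def test_ordering_preserved_and_validation(self):
        est = MassEstimate(mean=100, lower=80, upper=130)
        s = add_components(est, ArmourSpec(total_kg=12.5))
        assert s.lower <= s.mean <= s.upper
        with pytest.raises(DomainError):
            ArmourSpec(total_kg=-1.0)
        with pytest.raises(DomainError):
            ArmourSpec(total_kg=10.0, items=[("plate", 3.0)])


class TestLimbEquations:
    def test_synthetic_equation_analytic(self):
        """slope 2, intercept 0, grams: summed circumference 10 mm -> 0.1 kg."""
        eq = LimbEquation(id="synth", predictor="summed_circumference",
                          slopes=(2.0,), intercept=0.0, output_unit="g")
        m = SpecimenMeasurements("s", humeral_circumference_mm=4.0,
                                 femoral_circumference_mm=6.0)
        est = limb_mass(eq, m)
        assert est.mean == pytest.approx(0.1, rel=1e-12)
        assert est.lower == est.mean == est.upper  # pi_param 0 degenerates

    def test_separate_and_femur_only_predictors(self):
        eq2 = LimbEquation(id="sep", predictor="separate_circumferences",
                           slopes=(1.0, 2.0), intercept=-1.0, output_unit="kg")
        m = SpecimenMeasurements("s", humeral_circumference_mm=10.0,
                                 femoral_circumference_mm=100.0)
        assert limb_mass(eq2, m).mean == pytest.approx(10 ** (1 + 4 - 1), rel=1e-12)
        eqf = LimbEquation(id="fem", predictor="femur_circumference",
                           slopes=(3.0,), intercept=0.0, output_unit="kg")
        assert limb_mass(eqf, m).mean == pytest.approx(1e6, rel=1e-12)

    def test_missing_predictor_named(self):
        eq = LimbEquation(id="synth", predictor="summed_circumference",
                          slopes=(2.0,), intercept=0.0)
        with pytest.raises(DomainError, match="humeral_circumference_mm"):
            limb_mass(eq, SpecimenMeasurements("s", femoral_circumference_mm=6.0))

    def test_pi_methods(self):
        m = SpecimenMeasurements("s", humeral_circumference_mm=4.0,
                                 femoral_circumference_mm=6.0)
        pct = LimbEquation(id="p", predictor="summed_circumference", slopes=(2.0,),
                           intercept=0.0, output_unit="kg",
                           pi_method="percent_error", pi_param=25.0)
        est = limb_mass(pct, m)
        assert est.lower == pytest.approx(est.mean * 0.75)
        assert est.upper == pytest.approx(est.mean * 1.25)
        logse = LimbEquation(id="l", predictor="summed_circumference", slopes=(2.0,),
                             intercept=0.0, output_unit="kg",
                             pi_method="log_se", pi_param=0.1, pi_df=10)
        est = limb_mass(logse, m)
        from scipy import stats
        half = stats.t.ppf(0.975, 10) * 0.1
        assert est.upper / est.mean == pytest.approx(10**half, rel=1e-9)

    def test_registry_loads_and_guards_stubs(self):
        reg = load_equation_registry()
        eq = get_equation(reg, "synthetic_example")
        assert eq.output_unit == "g"
        with pytest.raises(RegistryError, match="Campione"):
            get_equation(reg, "CE2012_b")
        with pytest.raises(RegistryError, match="unknown"):
            get_equation(reg, "no_such_equation")

    def test_equation_validation(self):
        with pytest.raises(RegistryError):
            LimbEquation(id="x", predictor="summed_circumference",
                         slopes=(1.0, 2.0), intercept=0.0)
        with pytest.raises(RegistryError):
            LimbEquation(id="x", predictor="toe_length", slopes=(1.0,), intercept=0.0)


class TestDME:
    def test_identity_and_cube_law(self):
        est = MassEstimate(mean=1000, lower=800, upper=1300)
        same = dme_scale(est, 1000.0, 1000.0)
        assert same.mean == 1000
        half = dme_scale(est, 1000.0, 500.0)
        assert half.mean == pytest.approx(125.0)
        assert half.lower == pytest.approx(100.0)

    def test_published_style_example(self):
        est = MassEstimate(mean=1000, lower=1000, upper=1000)
        assert dme_scale(est, 1000.0, 800.0).mean == pytest.approx(512.0)

    def test_composition(self):
        est = MassEstimate(mean=1234.5, lower=900.0, upper=1700.0)
        via = dme_scale(dme_scale(est, 1000.0, 850.0), 850.0, 700.0)
        direct = dme_scale(est, 1000.0, 700.0)
        assert via.mean == pytest.approx(direct.mean, rel=1e-12)
        assert via.lower == pytest.approx(direct.lower, rel=1e-12)
        assert via.upper == pytest.approx(direct.upper, rel=1e-12)

    def test_domain_errors(self):
        est = MassEstimate(mean=1000, lower=800, upper=1300)
        with pytest.raises(DomainError):
            dme_scale(est, -1.0, 500.0)
        with pytest.raises(DomainError):
            dme_scale(est, 1000.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fl1=st.floats(100.0, 3000.0),
        fl2=st.floats(100.0, 3000.0),
        adult_fl=st.floats(100.0, 3000.0),
    )
    def test_composition_property(self, fl1, fl2, adult_fl):
        """Scaling adult -> FL1 -> FL2 equals scaling adult -> FL2."""
        est = MassEstimate(mean=1560.0, lower=1082.0, upper=2256.0)
        via = dme_scale(dme_scale(est, adult_fl, fl1), fl1, fl2)
        direct = dme_scale(est, adult_fl, fl2)
        assert via.mean == pytest.approx(direct.mean, rel=1e-9)


def test_volumetric_means_below_limb_equation_interval():
    """The published volumetric means all fall below the lower 95% PI of the
    bivariate limb-circumference estimate — the core discrepancy the
    ontogenetic correction resolves."""
    est = published_estimates()
    lower_ce = est.loc["CE2012_b", "lower"]
    for method in ("cvol_min", "cvol_pref", "cvol_max"):
        assert est.loc[method, "mean"] < lower_ce
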