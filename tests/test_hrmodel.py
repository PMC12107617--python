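"""Structural, drug-effect, covariate and IIV sub-models of the HR model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qtctbt as q
from qtctbt.hrmodel import ParameterError, boxcox_eta


class TestTimeEffect:
    def test_zero_at_treatment_start(self, published):
        assert q.time_effect(published, 0.0) == pytest.approx(0.0)

    def test_half_change_at_one_half_life(self, published):
        # (73.1 - 78.2) / 2 at t = Tprog
        assert q.time_effect(published, 7.74) == pytest.approx(-2.55, abs=1e-12)

    def test_asymptote(self, published):
        assert q.time_effect(published, 1e9) == pytest.approx(73.1 - 78.2)

    def test_pretreatment_clamps_to_zero(self, published):
        assert q.time_effect(published, -0.143) == 0.0

    def test_linear_form(self):
        spec = q.HRModelSpec(time_effect_form="linear", alpha=-0.3)
        assert q.time_effect(spec, 4.0) == pytest.approx(-1.2)

    def test_invalid_half_life(self, published):
        with pytest.raises(ParameterError):
            q.time_effect(published.updated(t_prog=-1.0), 1.0)


class TestCircadian:
    def test_peak_and_trough_of_24h_harmonic(self):
        spec = q.HRModelSpec(amp12=0.0)
        assert q.circadian(spec, spec.phi24) == pytest.approx(spec.amp24)
        assert q.circadian(spec, spec.phi24 - 12.0) == pytest.approx(-spec.amp24)

    def test_composite_amplitude_early_afternoon(self, published):
        # Published harmonics evaluated at 14.25 h (2.25 pm).
        assert q.circadian(published, 14.25) == pytest.approx(4.8240489, abs=1e-6)


class TestM2Effect:
    def test_zero_concentration(self, published):
        assert q.m2_effect(published, 0.0) == 0.0

    def test_half_maximum_at_ec50(self, published):
        assert q.m2_effect(published, 2600.0) == pytest.approx(0.179 / 2)

    def test_week2_mean_concentration_rounds_to_two_percent(self, published):
        frac = float(q.m2_effect(published, 300.0))
        assert frac == pytest.approx(0.0185172, abs=1e-6)
        assert round(100 * frac) == 2

    def test_negative_concentration_rejected(self, published):
        with pytest.raises(ValueError):
            q.m2_effect(published, -1.0)


class TestCovariates:
    def test_reference_value_gives_unity(self):
        assert q.covariate_factor(35.0, 35.0, -0.22) == pytest.approx(1.0)

    def test_low_albumin_raises_baseline_hr(self):
        assert q.covariate_factor(15.0, 35.0, -0.22) == pytest.approx(1.2049108, abs=1e-6)

    def test_conditional(self):
        assert q.conditional_factor(1, 0.0) == pytest.approx(1.0)
        assert q.conditional_factor(1, -0.047) == pytest.approx(0.953)
        assert q.conditional_factor(0, -0.047) == pytest.approx(1.0)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            q.covariate_factor(-5.0, 35.0, -0.22)


class TestIndividualParams:
    def test_zero_eta_returns_typical_values(self, published):
        ip = q.individual_params(published, {})
        assert ip["hr_base"] == published.hr_base
        assert ip["amp24"] == published.amp24
        assert ip["sigma_add"] == published.sigma_add

    def test_exponential_iiv(self, published):
        ip = q.individual_params(published, {"ec50": 1.0})
        assert ip["ec50"] == pytest.approx(7067.5328, abs=1e-3)

    def test_boxcox_limit_recovers_exponential(self):
        eta = 0.37
        assert boxcox_eta(eta, 1e-12) == pytest.approx(eta)
        assert boxcox_eta(eta, -0.77) == pytest.approx(math.expm1(-0.77 * eta) / -0.77)

    def test_shared_amplitude_eta_scales_both_harmonics(self, published):
        ip = q.individual_params(published, {"amp": 0.5})
        assert ip["amp24"] / published.amp24 == pytest.approx(ip["amp12"] / published.amp12)

    def test_unknown_effect_rejected(self, published):
        with pytest.raises(ParameterError):
            q.individual_params(published, {"nope": 1.0})


class TestPredictHr:
    def test_typical_baseline(self, ref_subject, published):
        spec = published.updated(amp24=0.0, amp12=0.0)
        assert q.predict_hr(ref_subject, spec, 0.0, 12.0, 0.0) == pytest.approx(78.2)

    def test_typical_recovered(self, ref_subject, published):
        spec = published.updated(amp24=0.0, amp12=0.0)
        assert q.predict_hr(ref_subject, spec, 1e9, 12.0, 0.0) == pytest.approx(73.1)

    def test_m2_composition(self, ref_subject, published):
        spec = published.updated(amp24=0.0, amp12=0.0)
        got = q.predict_hr(ref_subject, spec, 0.0, 12.0, 300.0)
        assert got == pytest.approx(78.2 * (1 - 0.0185172), abs=1e-3)

    def test_monotone_nonincreasing_in_concentration(self, ref_subject, published):
        concs = np.linspace(0, 8000, 50)
        hr = q.predict_hr(ref_subject, published, 2.0, 12.0, concs)
        assert np.all(np.diff(hr) <= 0)

    def test_monotone_nonincreasing_in_time(self, ref_subject, published):
        t = np.linspace(0, 30, 60)
        hr = q.predict_hr(ref_subject, published, t, 12.0, 0.0)
        assert np.all(np.diff(hr) <= 1e-12)

    def test_c209_study_effect_lowers_hr(self, published):
        spec = published.updated(amp24=0.0, amp12=0.0)
        s208 = q.SubjectProfile("a", study="C208")
        s209 = q.SubjectProfile("b", study="C209")
        h208 = q.predict_hr(s208, spec, 0.0, 12.0)
        h209 = q.predict_hr(s209, spec, 0.0, 12.0)
        assert h209 == pytest.approx(h208 * (1 - 0.047))


class TestStochasticSpec:
    @given(st.floats(0.01, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_cv_omega2_identity(self, cv):
        # CV = sqrt(e^(omega^2) - 1) and its inverse are a round trip.
        assert q.omega2_to_cv(q.cv_to_omega2(cv)) == pytest.approx(cv, rel=1e-12)

    def test_published_iiv_cvs(self, published):
        assert q.omega2_to_cv(published.omega2["hr_base"]) == pytest.approx(0.15)
        assert q.omega2_to_cv(published.omega2["amp"]) == pytest.approx(0.953)

    def test_omega_matrix_correlations(self, published):
        names, cov = published.omega_matrix()
        i, j = names.index("hr_base"), names.index("hr_rec")
        rho = cov[i, j] / math.sqrt(cov[i, i] * cov[j, j])
        assert rho == pytest.approx(0.41)

    def test_non_psd_correlation_rejected(self):
        spec = q.HRModelSpec(
            omega2={"hr_base": 0.02, "hr_rec": 0.02, "amp": 0.6},
            corr={("hr_base", "hr_rec"): 0.95, ("hr_base", "amp"): 0.95,
                  ("hr_rec", "amp"): -0.95},
        )
        with pytest.raises(ParameterError):
            spec.validate()
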