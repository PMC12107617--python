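"""Fixed-effect estimation, stepwise covariate selection and VPC."""

import numpy as np
import pytest

import qtctbt as q
from conftest import reference_covariates
from qtctbt.estimation import get_param


def _fixed_effect_design(n, seed, covariates=None):
    design = q.CohortDesign(
        n_subjects=n,
        placebo_fraction=1.0,
        c209_fraction=0.0,
        covariates=covariates or reference_covariates(),
    )
    return design


class TestFit:
    def test_structural_recovery_within_three_se(self):
        # No IIV, small residual noise: the structural parameters are
        # recovered to well within their standard errors.
        design = _fixed_effect_design(10, 0)
        truth = q.HRModelSpec(sigma_prop=0.02, sigma_add=0.5)
        cohort = q.make_cohort(design, seed=0)
        records = q.simulate_hr_observations(cohort, truth, design, seed=1)
        init = truth.updated(hr_base=85.0, hr_rec=68.0, t_prog=4.0)
        res = q.fit(records, cohort, init, ["hr_base", "hr_rec", "t_prog"])
        assert res.converged
        for name, true_val in (("hr_base", 78.2), ("hr_rec", 73.1), ("t_prog", 7.74)):
            est, se = get_param(res.estimates, name), res.se[name]
            assert abs(est - true_val) < 3 * se, name

    def test_refit_at_optimum_is_a_fixed_point(self):
        design = _fixed_effect_design(5, 2)
        truth = q.HRModelSpec(sigma_prop=0.03, sigma_add=0.8)
        cohort = q.make_cohort(design, seed=2)
        records = q.simulate_hr_observations(cohort, truth, design, seed=3)
        init = truth.updated(hr_base=82.0)
        first = q.fit(records, cohort, init, ["hr_base", "hr_rec"], compute_se=False)
        second = q.fit(records, cohort, first.estimates, ["hr_base", "hr_rec"],
                       compute_se=False)
        assert abs(second.ofv - first.ofv) < 0.05

    def test_fit_requires_two_subjects(self, ref_subject):
        records = [q.EcgRecord("ref", "C208", "active", 0.0, 12.0, "o", 1, 80.0)]
        with pytest.raises(ValueError):
            q.fit(records, [ref_subject], q.HRModelSpec(), ["hr_base"])

    def test_summary_lists_masked_parameters(self):
        design = _fixed_effect_design(4, 7)
        truth = q.HRModelSpec(sigma_prop=0.03, sigma_add=0.8)
        cohort = q.make_cohort(design, seed=7)
        records = q.simulate_hr_observations(cohort, truth, design, seed=8)
        res = q.fit(records, cohort, truth, ["hr_base"])
        text = res.summary()
        assert "hr_base" in text and "OFV" in text


class TestScm:
    def _simulate(self, albumin_effect, seed, n=24):
        cov = reference_covariates()
        cov["albumin_gL"] = (35.0, 0.25, 15.0, 49.0)
        design = _fixed_effect_design(n, seed, covariates=cov)
        truth = q.HRModelSpec(sigma_prop=0.04, sigma_add=1.0,
                              cov_albumin_exp=albumin_effect, cov_age_exp=0.0,
                              cov_ttp_exp=0.0, cov_weight_exp=0.0, cov_study=0.0)
        cohort = q.make_cohort(design, seed=seed)
        records = q.simulate_hr_observations(cohort, truth, design, seed=seed + 1)
        base = truth.updated(cov_albumin_exp=0.0)
        return records, cohort, base

    def test_empty_candidate_set_returns_base(self, ref_subject):
        records = [
            q.EcgRecord("ref", "C208", "active", float(t), 12.0, f"o{t}", 1, 80.0 - t)
            for t in range(5)
        ]
        twin = q.SubjectProfile("twin")
        records += [
            q.EcgRecord("twin", "C208", "active", float(t), 12.0, f"p{t}", 1, 79.0 - t)
            for t in range(5)
        ]
        base = q.HRModelSpec()
        spec, report = q.scm_step(records, [ref_subject, twin], base, [])
        assert spec == base and report == []

    def test_forward_selects_simulated_albumin_effect(self):
        records, cohort, base = self._simulate(albumin_effect=-0.22, seed=10)
        spec, report = q.scm_step(
            records, cohort, base, ["cov_albumin_exp", "cov_age_exp"],
            direction="forward",
        )
        assert get_param(spec, "cov_albumin_exp") != 0.0
        dofv = {r["candidate"]: r["dofv"] for r in report if r["step"] == "forward"}
        assert dofv["cov_albumin_exp"] > 3.84

    def test_null_data_keeps_base_model(self):
        records, cohort, base = self._simulate(albumin_effect=0.0, seed=20)
        spec, _ = q.scm_step(
            records, cohort, base, ["cov_albumin_exp"], direction="forward"
        )
        assert get_param(spec, "cov_albumin_exp") == 0.0

    def test_backward_removes_spurious_effect(self):
        records, cohort, base = self._simulate(albumin_effect=0.0, seed=30)
        start = base.updated(cov_albumin_exp=0.05)
        spec, _ = q.scm_step(
            records, cohort, start, ["cov_albumin_exp"], direction="backward"
        )
        assert get_param(spec, "cov_albumin_exp") == 0.0


class TestVpc:
    def _dataset(self, model, n=12, seed=0):
        design = q.CohortDesign(n_subjects=n)
        cohort = q.make_cohort(design, seed=seed)
        records = q.simulate_hr_observations(cohort, model, design, seed=seed + 1)
        return records, cohort

    def test_reproducible_with_fixed_seed(self):
        model = q.published_model_spec(("hr_base",))
        records, cohort = self._dataset(model, n=6, seed=40)
        a = q.vpc(records, cohort, model, n_sim=100, seed=11)
        b = q.vpc(records, cohort, model, n_sim=100, seed=11)
        assert a.equals(b)

    def test_bands_collapse_without_variability(self):
        model = q.HRModelSpec(sigma_prop=0.0, sigma_add=0.0)
        records, cohort = self._dataset(model, n=4, seed=41)
        out = q.vpc(records, cohort, model, n_sim=100, seed=12)
        assert np.allclose(out["sim_lo"], out["sim_hi"])
        assert np.allclose(out["observed"], out["sim_median"])

    def test_observed_percentiles_mostly_inside_bands(self):
        # The observed data are one replicate from the simulation model, so
        # the bands should cover the observed percentiles in ~95% of cells.
        model = q.published_model_spec(("hr_base", "hr_rec"))
        records, cohort = self._dataset(model, n=25, seed=42)
        out = q.vpc(records, cohort, model, n_sim=120, seed=13)
        inside = (out["observed"] >= out["sim_lo"]) & (out["observed"] <= out["sim_hi"])
        assert inside.mean() >= 0.8

    def test_nsim_floor(self):
        model = q.published_model_spec(("hr_base",))
        records, cohort = self._dataset(model, n=4, seed=43)
        with pytest.raises(ValueError):
            q.vpc(records, cohort, model, n_sim=10)
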