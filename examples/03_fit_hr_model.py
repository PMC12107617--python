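"""Fit the heart-rate model to a simulated cohort by marginal ML.

Simulates a small cohort from the published parameter values, then
re-estimates the structural time-on-treatment parameters by Laplace-based
marginal maximum likelihood starting from deliberately wrong values, and
prints the fitted parameter table.  (Small cohort for speed; estimates
carry corresponding sampling error.)
"""

import qtctbt as q
from qtctbt.experiments import reference_covariates

design = q.CohortDesign(
    n_subjects=40, placebo_fraction=1.0, c209_fraction=0.0,
    covariates=reference_covariates(),
)
truth = q.published_model_spec(("hr_base", "hr_rec"))
cohort = q.make_cohort(design, seed=7)
records = q.simulate_hr_observations(cohort, truth, design, seed=8)

init = truth.updated(hr_base=85.0, hr_rec=65.0, t_prog=4.0,
                     omega2={"hr_base": 0.05, "hr_rec": 0.05},
                     sigma_prop=0.12, sigma_add=1.5)
res = q.fit(records, cohort, init,
            ["hr_base", "hr_rec", "t_prog", "omega2_hr_base", "omega2_hr_rec",
             "sigma_prop", "sigma_add"])
print(res.summary())
print()
print("Simulation truth: baseline HR 78.2 bpm, recovered HR 73.1 bpm,")
print("recovery half-life 7.74 weeks, IIV variances 0.0223/0.0234,")
print("residual 8.4% proportional + 2.7 bpm additive per occasion.")
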