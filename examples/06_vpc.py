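"""Visual predictive check of the heart-rate model.

Simulates an observed dataset, then re-simulates it 150 times under the
model and prints, per time bin, the observed 2.5th/50th/97.5th HR
percentiles next to the 95% band of each simulated percentile.
"""

import qtctbt as q

design = q.CohortDesign(n_subjects=50)
model = q.published_model_spec(("hr_base", "hr_rec"))
cohort = q.make_cohort(design, seed=21)
records = q.simulate_hr_observations(cohort, model, design, seed=22)

bands = q.vpc(records, cohort, model, n_sim=150, seed=23)
print(f"{'bin':<14}{'pctl':>6}{'observed':>10}{'band low':>10}{'band high':>10}")
for _, r in bands.iterrows():
    flag = "" if r["sim_lo"] <= r["observed"] <= r["sim_hi"] else "  *outside*"
    print(f"{r['bin']:<14}{r['percentile']:>6.1f}{r['observed']:>10.1f}"
          f"{r['sim_lo']:>10.1f}{r['sim_hi']:>10.1f}{flag}")

print()
print("The observed data are one draw from the model, so observed")
print("percentiles should fall inside their simulation bands in ~95% of")
print("cells; systematic excursions would indicate model misfit.")
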