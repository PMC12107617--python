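"""Simulate a virtual MDR-TB trial cohort and inspect its structure.

Draws a 60-subject cohort with trial-like covariates, heart rate from the
published mixed-effects model (baseline/recovered-HR variability) and QT
generated under the true time-varying QT-HR relationship, then prints a
few summaries and writes the long-format ECG table.
"""

import numpy as np

import qtctbt as q

design = q.CohortDesign(n_subjects=60)
model = q.published_model_spec(("hr_base", "hr_rec"))  # reduced-IIV stochastic model
records, cohort = q.make_dataset(design, model, seed=42)
df = q.records_to_frame(records, cohort)

print(f"subjects: {len(cohort)}   ECG replicates: {len(df)}")
print(f"arms: {df.groupby('arm')['subject_id'].nunique().to_dict()}")
print("covariate medians:",
      {c: round(float(df.groupby('subject_id')[c].first().median()), 1)
       for c in ('age_y', 'weight_kg', 'albumin_gL', 'ttp_mgit_h')})

pre = df[df["t_weeks"] < 0]["hr_bpm"]
late = df[df["t_weeks"] >= 20]["hr_bpm"]
print(f"mean HR pretreatment: {pre.mean():.1f} bpm -> weeks 20+: {late.mean():.1f} bpm")
wk2 = df[(df['t_weeks'] == 2.0) & (df['arm'] == 'active')]['conc_m2']
print(f"mean M2 concentration at week 2 (active arm): {wk2.mean():.0f} ng/mL")

import pathlib

out = pathlib.Path("scratch")
out.mkdir(exist_ok=True)
q.write_ecg_table(records, out / "cohort.csv", subjects=cohort)
print(f"wrote {out / 'cohort.csv'} (long format, one row per ECG replicate)")
print()
print("Heart rate starts elevated (~78 bpm, active TB) and normalises")
print("towards ~73 bpm as treatment succeeds; the metabolite concentration")
print("accumulates to ~300 ng/mL by week 2, mirroring the trial design the")
print("model was estimated on.")
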