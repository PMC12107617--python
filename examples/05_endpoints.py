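"""Standard QTc endpoints on the placebo arm: why the correction matters.

Simulates a two-arm cohort with NO drug effect on QT, then summarises the
change from baseline (dQTc) in the placebo arm per time bin for Fridericia
vs the time-varying correction, and the placebo-corrected ddQTc.
"""

import qtctbt as q

design = q.CohortDesign(n_subjects=150)
model = q.published_model_spec(("hr_base", "hr_rec"))
records, cohort = q.make_dataset(design, model, seed=11)
df = q.records_to_frame(records, cohort)

plac = df[df["arm"] == "placebo"]
out = q.summarize(plac, methods=("fridericia", "tbt"))
delta = out[out["kind"] == "delta"]
print("placebo-arm mean dQTc (ms) by bin:")
print(f"{'bin':<10}{'QTcF':>10}{'QTcTBT':>10}")
for b in delta["bin"].unique():
    sub = delta[delta["bin"] == b].set_index("method")
    print(f"{b:<10}{sub.loc['fridericia', 'mean']:>10.2f}{sub.loc['tbt', 'mean']:>10.2f}")

dd = q.delta_delta_qtc(df, "tbt")
print("\nplacebo-corrected ddQTcTBT (ms):")
for _, r in dd.iterrows():
    print(f"  {r['bin']:<10} {r['mean']:>6.2f}  [{r['ci_low']:.2f}, {r['ci_high']:.2f}]")

print()
print("No QT-prolonging drug is simulated, yet Fridericia's dQTc drifts")
print("upward over the treatment period (heart rate normalises, and a")
print("too-small exponent underestimates baseline QTc at elevated HR).")
print("The time-varying correction stays centred near zero, and ddQTc")
print("(placebo-corrected) is compatible with zero for either method.")
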