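"""Evaluate correction quality: per-bin QTc-vs-HR slopes and the slope trend.

Simulates a cohort whose QT follows the true time-varying QT-HR
relationship, corrects with Bazett, Fridericia, Olliaro and the
time-varying method, and prints each method's slope-trend summary plus the
number of time bins whose slope CI covers zero (8 = perfect correction).
"""

import qtctbt as q

design = q.CohortDesign(n_subjects=200)
model = q.published_model_spec(("hr_base", "hr_rec"))
records, cohort = q.make_dataset(design, model, seed=3)

report = q.evaluate_corrections(records, methods=("bazett", "fridericia",
                                                  "olliaro", "tbt"))
print(f"{'method':<12}{'bins covering 0':>16}{'slope at t=0':>14}{'drift /wk':>12}")
for method, trend in report.trends.items():
    print(f"{method:<12}{report.bins_covering_zero[method]:>13}/8 "
          f"{trend.intercept:>13.3f} {trend.trend:>11.4f}")

print()
print("A successful correction leaves QTc independent of HR: slopes ~0 in")
print("every bin, intercept (slope at treatment start) ~0 and no drift over")
print("time.  Bazett overcorrects (positive slopes), Fridericia")
print("undercorrects early (negative intercept), Olliaro is right at the")
print("start but overcorrects later; the time-varying method stays flat")
print("throughout.")
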