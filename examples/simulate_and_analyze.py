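"""Simulate a biomarker cohort and run the default ROC analysis.

Draws a 300-subject cohort (150 cases ~ N(55, 10), 150 controls
~ N(40, 10)), builds the empirical ROC curve, picks the Youden-optimal
cutoff and prints the performance row.
"""

import rocreport as rr

config = rr.SimulationConfig(seed=42)
cohort = rr.simulate_cohort(config)

curve = rr.build_roc(cohort)
optimum = rr.youden(curve)
table = rr.performance_row(cohort, optimum, curve)

print(f"Cohort: {cohort.n_positive} cases / {cohort.n_negative} controls")
print(f"Theoretical (binormal) AUC: {rr.theoretical_auc(config):.4f}")
print(f"Empirical AUC: {curve.auc:.4f}  "
      f"[{curve.auc_ci_lower:.4f}, {curve.auc_ci_upper:.4f}] (DeLong 95% CI)")
print(f"Youden cutoff: {optimum.threshold:.3f}  (J = {optimum.criterion_value:.3f})")
print()
print(table.render_text())
print()
print("The cutoff is the marker value above which a subject is called a case;")
print("J = sensitivity + specificity - 1 is the distance above chance there.")
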