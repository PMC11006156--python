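"""DeLong and bootstrap confidence intervals for the AUC.

The DeLong interval is a Wald interval using the nonparametric
placement-value variance of the empirical AUC; the stratified percentile
bootstrap is the small-sample alternative. The two agree closely at
moderate n.
"""

import rocreport as rr

cohort = rr.simulate_cohort(rr.SimulationConfig(seed=42))
auc = rr.build_roc(cohort).auc

for level in (0.95, 0.99):
    lo, hi = rr.auc_ci_delong(cohort, level=level)
    print(f"DeLong    {level:.0%} CI: [{lo:.4f}, {hi:.4f}]")
lo_b, hi_b = rr.auc_ci_bootstrap(cohort, level=0.95, n_boot=2000, seed=0)
print(f"Bootstrap  95% CI: [{lo_b:.4f}, {hi_b:.4f}]  (2000 resamples)")
print(f"Point estimate: AUC = {auc:.4f}")
print()
print("Wider level, wider interval; the 99% interval always contains the 95%.")
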