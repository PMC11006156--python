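# rocreport

ROC curve analysis and optimal cutoff selection for a single continuous
biomarker against a binary outcome, with full diagnostic performance
tables, a two-class Gaussian cohort simulator and an automated, sectioned
analysis report. It is aimed at biostatisticians and clinical researchers
who need a scriptable, reproducible version of the point-and-click ROC
workflow: load a CSV, pick a cutoff method, read off sensitivity,
specificity, predictive values and the AUC with its confidence interval.

## The statistics

For a marker X and binary outcome Y (1 = case), each threshold c induces
the classification rule "call positive if X > c" and the empirical rates

- sensitivity(c) = P̂(X > c | Y = 1), specificity(c) = P̂(X ≤ c | Y = 0).

Candidate thresholds are the midpoints of consecutive distinct marker
values (plus ∓∞ sentinels), and the ROC curve plots sensitivity against
1 − specificity over all of them. The trapezoidal area under the curve
(AUC) equals the Mann–Whitney probability P(X₁ > X₀) + ½P(X₁ = X₀) for a
random case/control pair; its confidence interval is the DeLong interval,
AUC ± z·SE with the SE from placement-value variances (a stratified
percentile bootstrap is available as an alternative).

Cutoff selection implements five method families:

- **Youden's J** — maximize J = sensitivity + specificity − 1;
- **closest top-left** — minimize d = (1 − sens)² + (1 − spec)²;
- **constrained maximization** — maximize sensitivity subject to
  specificity ≥ bound (or vice versa);
- **minimum p-value** — maximize the uncorrected 2×2 Pearson chi-square of
  predicted-vs-actual class over all dichotomizations (a procedure with a
  known Type I inflation, flagged in every report);
- **biomarker-oriented** — the pooled marker mean, median or mode;

plus a manual pass-through cutoff. Ties are always broken toward the
smallest threshold.

The simulator draws binormal cohorts — by default 300 subjects, half
cases from N(55, 10) and half controls from N(40, 10), on the scale of
the hepatic steatosis index (HSI) used in NAFLD screening — for which the
theoretical AUC is Φ((μ₁−μ₀)/√(σ₁²+σ₀²)) ≈ 0.8556.

## Worked example

```python
import rocreport as rr

config = rr.SimulationConfig(seed=42)
cohort = rr.simulate_cohort(config)
curve = rr.build_roc(cohort)
optimum = rr.youden(curve)
print(rr.performance_row(cohort, optimum, curve).render_text())
```

prints (see `examples/simulate_and_analyze.py` for the full script):

```
Cohort: 150 cases / 150 controls
Theoretical (binormal) AUC: 0.8556
Empirical AUC: 0.8696  [0.8290, 0.9103] (DeLong 95% CI)
Youden cutoff: 44.572  (J = 0.660)

Threshold  Sensitivity  Specificity  PPV   NPV   Accuracy  AUC   CI:LB  CI:UB
44.57      0.89         0.77         0.79  0.88  0.83      0.87  0.83   0.91
```

The cutoff 44.57 is the marker value above which a subject is called a
case; at that cutoff 89% of cases and 77% of controls are classified
correctly, a positive call is right 79% of the time, and the marker's
overall discrimination is AUC 0.87 with 95% CI [0.83, 0.91]. Other
capabilities are shown in `examples/`: `cutoff_methods_tour.py` (all
selector families side by side), `confidence_intervals.py` (DeLong vs
bootstrap), `offline_report.py` (the deterministic report pipeline).

The same pipeline is available from the shell:

```
rocreport simulate --seed 42 --out cohort.csv
rocreport analyze  --input cohort.csv --marker HSI --outcome NAFLD --outdir out/
rocreport report   --input cohort.csv --marker HSI --outcome NAFLD \
                   --outdir rep/ --transport offline --format html
rocreport validate --input cohort.csv --marker HSI --outcome NAFLD
```

`analyze` writes the data preview, marker and class summaries, the curve
(JSON), figures (PNG/SVG) and the performance table (CSV/JSON) plus a
manifest sufficient to reproduce the run; `report` adds the sectioned
report (disclaimer first; Introduction, Results with data-quality /
ROC-plot / performance subsections, Conclusion) and a JSON-lines prompt
log. Report narration is produced by a pluggable transport: the default
offline stub is deterministic and needs no network; a remote
chat-completion transport can be configured with the API key taken from
the environment only. `validate` prints the four metrics (AUC, Youden
threshold, specificity, sensitivity) used to compare against other ROC
software on a locally supplied dataset.

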