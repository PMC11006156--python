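# Methods

## Data model

The analysis unit is a pair (X, Y): a continuous marker X and a binary
outcome Y read from a comma-separated file with a mandatory header row.
Missing tokens are the empty string, `NA` and `NaN` (case-insensitive);
a row missing either cell is dropped whole and counted, because a
marker/outcome pair is unusable when either half is absent. The preview
panel's missing percentage is instead cell-based (missing cells over all
cells of the raw table) — it describes data quality of the file, not of
the analysis subset. The outcome must carry exactly two distinct labels;
when the user does not name the positive class, label `1` is positive for
{0, 1} outcomes and otherwise the lexicographically larger label, a
deterministic default that matches the common 0/1 and benign/malignant
conventions and can always be overridden.

## ROC construction

Candidate thresholds are the midpoints of consecutive distinct marker
values, extended by −∞ and +∞ sentinels so the curve always contains the
trivial operating points (sens 1, spec 0) and (sens 0, spec 1). The
classification rule is strict (`X > c` positive under
`greater_is_positive`, `X < c` under `less_is_positive`): at midpoints a
tie between marker and threshold is impossible by construction, and a
user-supplied manual cutoff equal to an observed value classifies that
value negative. Orientation is auto-detected as the direction with
AUC ≥ 0.5 (recorded on the curve) and can be forced.

The AUC is the trapezoidal area over (1 − specificity, sensitivity).
Over the midpoint grid this is algebraically identical to the
Mann–Whitney pair-counting probability with ties weighted ½; the test
suite verifies the identity against a brute-force pair count and against
an independent library implementation on randomized datasets.

## AUC confidence interval

The default interval is DeLong's: placement values are computed by the
midrank formulation, their between-subject variances give
Var(AUC) = S₁₀/m + S₀₁/n, and a normal-quantile Wald interval is clipped
to [0, 1]. Perfectly separated classes have zero placement variance and
a degenerate (1, 1) interval. A stratified percentile bootstrap (default
2,000 resamples) is provided for small samples. Which interval the
original point-and-click tools report is generally undocumented; DeLong
is this package's default because it is the de-facto standard of the R
ROC ecosystem and reproduces the symmetric ±0.04-style intervals seen in
practice at n = 150 per class. When one class has a single member the
curve is still built but the interval is set to the uninformative (0, 1);
calling the interval routines directly raises instead.

## Cutoff selection

All selectors break ties toward the smallest threshold — deterministic,
and favouring sensitivity for greater-is-positive markers. Youden's J
and the closest-top-left distance are evaluated on every curve point.
Constrained maximization implements lower bounds only (metric ≥ bound),
mirroring the "minimum constraint value" idiom of the GUI tools it
replaces; an infeasible bound is an error, not a silent fallback.

The minimum-p-value selector forms, at every interior midpoint, the 2×2
table of predicted vs actual class and computes the uncorrected Pearson
chi-square (1 df); interior midpoints always have positive margins, so
no degenerate tables arise (a constant marker is rejected). The selected
p-value is reported raw, with no multiplicity correction — the procedure
is deliberately the classical minimum-p dichotomization, whose Type I
inflation is real: a seeded simulation in the test suite demonstrates a
null rejection rate well above the nominal 0.05, and every generated
report carries a caveat sentence in its disclaimer.

Biomarker-oriented cutoffs use the pooled marker mean, median or mode.
The mode of continuous data is not well defined; here, if any value
repeats, the most frequent value wins (smallest on ties), otherwise the
midpoint of the modal bin of a Freedman–Diaconis histogram — a scale-free
binning that needs no tuning parameter.

## Performance measures

The confusion matrix at the selected cutoff yields sensitivity,
specificity, PPV, NPV and accuracy; PPV/NPV are reported as `NA` when no
subject is called positive (resp. negative) rather than as 0/0. Internal
values are full precision; rendered tables round to 2 decimals and the
report prompts to 3 (AUC to 4), matching the table-vs-prose precision
convention of clinical reporting. The identities
ppv = sens·p / (sens·p + (1−spec)(1−p)) and
accuracy = sens·p + spec·(1−p) (p = prevalence) hold exactly for every
computed row and are enforced as properties in the tests.

## Simulator

The generator draws two independent Gaussian classes. Defaults — 300
subjects, prevalence 0.5, cases N(55, 10), controls N(40, 10), marker
named HSI — emulate a screening-biomarker cohort for non-alcoholic fatty
liver disease; prevalence 0.5 is the unique value consistent with the
reference accuracy/sensitivity/specificity triple (0.733·p +
0.893·(1−p) = 0.813 ⇒ p = 0.5). The theoretical AUC of the binormal
model, Φ((μ₁−μ₀)/√(σ₁²+σ₀²)) ≈ 0.8556 at the defaults, serves as the
closed-form oracle for convergence tests. Sampling uses numpy's PCG64
generator with an explicit seed in every output; no global RNG state is
read or written. Simulated values are unbounded — the generator makes no
attempt at marker realism (no truncation, no skew, no measurement
rounding), so passing tests say nothing about heavy-tailed or discretized
real markers.

What the simulation-based tests show: that the analysis pipeline
reproduces the distributional behaviour of the stated generator (AUC
center ≈ 0.856, Youden-threshold center ≈ 47.5 — the crossing point of
two equal-variance densities — with single-realization values such as
AUC 0.8703 / threshold 45.326 inside the central 99% replicate envelope).
What they do not show: calibration on real cohorts, robustness to
non-Gaussian markers, or covariate effects.

## Report pipeline

A report is five ordered parts — Introduction; Results with Data Quality
Checking, ROC Plot and Performance Measures subsections; Conclusion —
preceded always by a disclaimer (rendering refuses a spec without one).
Section narration comes from dispatching one prompt per section through a
transport. Default (v1) prompts are fixed templates filled from the
computed results, using the user's column names verbatim; custom (v2)
prompts replace any subset of slots, with empty slots falling back to the
defaults, and an unknown placeholder is an error naming the placeholder.
Every numeric placeholder equals the corresponding table/summary value
after the documented rounding — prompts never recompute statistics.

By default the two data-quality prompts are merged into one call, so a
report costs five transport calls; a switch dispatches all six
separately. A transport failure in one section degrades to a placeholder
interpretation for that section only. The offline stub transport is a
pure function of (section, prompt) and records a fixed epoch timestamp,
making the whole simulate → analyze → report pipeline byte-deterministic
given data and configuration — this is the package's reproducibility
contract and is asserted in the tests. The remote transport (a
chat-completion endpoint, default model string `gpt-3.5-turbo`,
configurable) reads its API key from the environment only, never from
config or logs, and is not exercised by the test suite. Prompt/response
logging is always on, as JSON lines.

## Numerical and design notes

- Operating points are computed by `searchsorted` counting on sorted
  class arrays — O((m+n) log(m+n)) per curve, exact rational counts.
- Chi-square selection is evaluated vectorized from the same counts; the
  test oracle recomputes each table through an independent contingency
  routine. Mathematically tied maxima can differ across implementations
  in the last float bits, so oracle comparisons resolve ties with a 1e-9
  tolerance.
- Quartiles use linear interpolation; boxplot whiskers are Tukey
  1.5·IQR; densities use a Gaussian kernel with Silverman bandwidth —
  the defaults of the plotting stacks practitioners compare against.
- Problem sizes in the test and acceptance runs (1,000 replicates of
  n = 300; 1,000 coverage simulations at n = 50 per class; 500 random
  oracle datasets of n ≤ 30) were chosen as the smallest sizes at which
  the Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

Single marker only (no multi-marker panels, no covariate adjustment); no
smoothed or binormal-fitted ROC curves; no partial AUC; no confidence
intervals for sensitivity/specificity/PPV/NPV; no missing-data
imputation; comma-separated input only. The external `validate`
subcommand compares against other tools on a user-supplied local file —
the package does not download or redistribute clinical datasets.
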