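# Methods

## Scope and data

The package evaluates a binary staging test (a fibroblast-activation-protein
PET/CT scan) against a composite reference standard (staging laparoscopy
plus peritoneal washing cytology) in a cohort of 109 patients with locally
advanced gastric adenocarcinoma, and models the economic consequences of
four staging strategies. No per-patient data are shipped: the only real
inputs are the published aggregates packaged in `opmstage.study` — the 2×2
table (12, 5, 4, 88), the reference-positive subtype split (7 P1CY1,
6 P1CY0, 3 P0CY1), the stage-migration split among the 17 index-positive
patients (5 IIB, 10 III, 2 IVA), the uptake summaries by group, and the
three per-patient cost aggregates ($9,550.50; −$727.60; +$251.70).
Everything else is recomputed or simulated.

## Diagnostic accuracy

Point metrics are the usual 2×2 ratios. Undefined metrics (empty
denominator) are reported as an explicit `undefined` marker, never as 0.
Interval choices:

* **Proportions** — Wilson score interval by default, Clopper–Pearson as an
  option (`statsmodels.stats.proportion` supplies both). Wilson was chosen
  as the default for its small-sample behaviour; the source report does not
  name its method. Coverage of the default at the cohort's margins is
  checked by simulation (≥ 92% empirical coverage at n = 92, p = 0.95 over
  10,000 draws).
* **AUC** — the test is binary, so no multi-threshold ROC exists; the AUC is
  the single-threshold trapezoid (sens + spec)/2 with a Hanley–McNeil
  standard error (n_pos = TP+FN, n_neg = FP+TN) and a normal interval
  clipped to [0, 1].
* **Display** — percentages round half away from zero to 1 decimal
  (the "75.0%" style); currency to 2 decimals, compared at $0.005.

Two published headline values do not follow from the published table by the
stated formulas: LR⁺ prints as 14.2 where sens/(1−spec) on the table gives
13.95, and the AUC prints as 0.83 (CI 0.72–0.94) where (sens+spec)/2 gives
0.848. The package reports the formula values and annotates the gap in the
`reproduce` report rather than imitating the prints; the rounding or
software path behind the printed values is not stated in the source.

## Cost model

Each strategy is a finite tree of chance nodes (branch probabilities = the
observed cohort frequencies, validated to sum to 1 within 1e−9) and
terminal nodes carrying a cost (sum of unit procedure costs on the path)
and event tags (`pet`, `laparoscopy`, `gastrectomy`, `reference_positive`).
Expected cost is the probability-weighted sum over root-to-leaf paths —
exact, no simulation. Cohort tallies are expected counts (frequency × n),
not resampled integers.

Decision rules: a patient found metastatic by the strategy's decision rule
is spared gastrectomy. Under S4, laparoscopy arbitrates PET-positives, so
the 5 PET-positive / laparoscopy-negative patients proceed to gastrectomy.
"Futile gastrectomy prevented" is a reference-positive patient spared
gastrectomy under the strategy (S4: the 12 true positives, 11% of 109);
"missed OPM" is a reference-positive patient who still undergoes
gastrectomy (S4: the 4 false negatives). This definition reproduces the
published 11%; the source's own prose assigns "16 futile gastrectomies" to
S2 and "17" to S3 under a different (spared-by-nobody) reading — only the
definition above is computed.

Unit costs are back-derived from the published aggregates by the triangular
system c_gast = S1 total; S1+S3Δ = c_pet + (92/109)·c_gast; S1+S2Δ =
c_lap + (93/109)·c_gast, giving c_pet = $761.93, c_lap = $1,653.61. Forward
evaluation then reproduces S2−S3 = $979.30 to the cent by construction.
The published S4 saving of $232.30 is *not* reproducible from these inputs:
the stated branch structure forward-evaluates to $283.30. A plausible cause
is different postoperative-day accounting when laparoscopy immediately
precedes gastrectomy, but the source does not say; the model reports its
own value with an annotation. Non-positive back-solved costs are rejected
as inconsistent aggregates.

## Sensitivity analyses

The model is re-parameterised by rates (prevalence, sensitivity,
specificity) plus unit costs, so perturbed parameters always define a
coherent joint branch distribution; at the observed rates this reproduces
the count-based trees exactly.

* **One-way sweeps** rebuild the model at each grid value; curves satisfy
  the analytic Lipschitz bound (≤ c_gast·Δprev per step for prevalence).
* **Break-even** uses bisection on a bracketed interval (tolerance-driven,
  robust); the returned threshold re-evaluates to a cost difference below
  $0.01. The S3-vs-S1 prevalence threshold at the derived costs is ≈ 0.037:
  below ~3.7% prevalence, scanning everyone no longer pays for itself.
* **PSA** — probability parameters default to Beta(successes+1, failures+1)
  from the observed counts; costs default to Gamma with the observed mean
  and a 10% coefficient of variation (the source gives no uncertainty
  model; these conventional defaults are overridable, including point
  masses). Draws come from `numpy.random.default_rng(seed)` in a fixed
  parameter order, so results are bitwise reproducible for a given (seed,
  draw count, distribution set). Ties for "cheapest" break toward the
  earlier strategy id. Under the defaults, the PET-only strategy is
  cheapest in ≈ 99% of draws.

## Synthetic cohorts

`generate_cohort` emulates the study's data structure: true OPM status ~
Bernoulli(prevalence = 16/109); the index test ~ Bernoulli(sens = 0.75)
given disease and Bernoulli(1−spec), spec = 88/93, otherwise; subtypes for
positives from the (7, 6, 3)/16 mixture; initial stages from a (5, 10, 2)/17
mixture over (IIB, III, IVA), calibrated so the expected index-positive
stage-migration split matches the observed 5/10/2; primary-tumour SUVmax
and target-to-background ratios from group-specific normals truncated at
zero (OPM 18.49 ± 6.00 vs no-OPM 14.25 ± 5.95 for SUVmax), parameterised
from the published mean ± SD only. The reference standard is modelled as
perfect (`lap_result = true_opm`) because the analysis adopts it as ground
truth; an optional laparoscopy false-negative rate (default 0) covers the
2.8%–17.2% range reported for the procedure, and an optional
`cytology_blind` flag forces cytology-only (P0CY1) disease PET-negative,
reflecting that 3 of the 4 observed false negatives were cytology-only.
The final stage is IVB exactly when the reference call is positive.

The stage-migration tally counts the upstaging the *index test* induces:
every index-positive patient migrates initial stage → IVB in the tally,
whatever the reference standard later concludes (that is what the observed
17/109 = 15.6% measures); the per-record `final_stage` field, by contrast,
follows the reference arbiter.

What the generator does **not** emulate: lesion geometry or image
statistics, correlation between uptake and test positivity (uptake is drawn
from the disease-group distribution independently of the PET call), per-site
metastasis locations, and covariate structure (age, histology). Passing
tests therefore show internal consistency of the pipeline under the stated
sampling model, not robustness to real-data complications such as
reader variability or spectrum effects.

A deterministic `reference_cohort()` reconstructs a 109-patient cohort
matching the published 2×2 table, subtype split and migration split exactly
(uptake set to group means); it is synthetic — a constructed stand-in used
for fixtures and the reproduction report, not patient data.

## Numerical choices and problem sizes

Currency is floating point with cent display and $0.005 comparison
tolerance; branch probabilities validate to 1e−9; tree-vs-enumeration
equivalence is asserted at 1e−9. The test suite's simulation sizes —
10,000 PSA draws, 10,000 coverage draws, 2,000 power replicates, one
100,000-patient recovery cohort — were chosen to make Monte-Carlo error
negligible relative to the asserted tolerances (3 binomial/MC standard
errors) while keeping the suite fast.

## Known limitations

* Cost-only model: no effectiveness axis, no QALYs, no discounting, single
  episode of care — so no acceptability curves.
* The composite reference standard is treated as truth; its own
  false-negative rate enters only through the optional simulation knob.
* The four published per-patient uptake summaries cannot be disaggregated
  (16 OPM patients share one uptake group, including the 4 the scan
  missed), so the generator treats OPM as a single uptake group.
* Group comparison offers pooled (Student) and Welch t tests only, matching
  the source's analysis plan; degenerate (zero-variance) inputs return an
  explicit NaN marker.
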