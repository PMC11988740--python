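# Methods

This note documents the statistical procedures implemented in `mammowatch`,
the assumptions behind the synthetic-data generator, the numerical choices,
and the known limitations.

## Evaluation model

The subject of evaluation is a mammography AI model that returns, per
study, a probability of malignancy in [0, 1] (one score per breast; the
study score is the maximum of the two). Ground truth is a binary pathology
class; when only a BI-RADS category is available, categories 1–2 map to
"without pathology" and 3–6 to "with pathology". BI-RADS 6 (biopsy-proven
malignancy) is included on the positive side as a deliberate choice: it is
the one category whose positivity is certain, and excluding it would
discard exactly the studies with the strongest reference standard.

### Threshold rule and ROC construction

Calls use the inclusive rule: score ≥ threshold ⇒ positive. The ROC curve
therefore has one operating point per distinct observed score (threshold at
that score) plus the (0, 0) point at a sentinel above the maximum — this
candidate set is exactly the set of achievable operating points, so an
exhaustive search over it is exact, not approximate. AUC is the trapezoidal
integral over FPR, which equals the Mann–Whitney concordance probability
with tied positive–negative pairs credited 0.5; the test suite verifies
this equivalence exhaustively on small instances and against an independent
library implementation. The operating point maximizes the Youden index
J = sensitivity + specificity − 1; among ties the smallest threshold wins,
which favors sensitivity — the appropriate direction in a screening
context, where a missed cancer is costlier than a recall.

Metrics with a zero denominator (specificity without negatives, precision
without positive calls) are explicitly undefined (`None`/`null`), never
silently zero, and are excluded from deviation checks.

### Calibration testing

Calibration testing compares the obtained metric set with the metrics the
developer claims. Two criteria apply: AUC ≥ `auc_min` (default 0.81), and
for every claimed metric a maximum *downward relative* deviation of 10%:
100 · (obtained − claimed)/claimed < −10 is a violation. The deviation rule
is relative (percent of the claimed value), not absolute percentage points,
matching how relative-difference columns are conventionally printed.
Boundary values pass (criteria are "met or exceeded"); upward deviations
never violate; unclaimed (NA) metrics are skipped — in particular, AUC is
governed solely by the floor when the developer claims no AUC. Verdicts use
unrounded deviations; half-away-from-zero rounding (0 decimals by default,
1 via option) is display-only, so a −10.4% deviation printed as −10% still
fails.

With a 100-study cohort the verdict is noticeably stochastic: the in-sample
Youden threshold can land on an unbalanced operating point, pushing one of
sensitivity/specificity more than 10% below its claim even when the model's
true characteristics match them. This is a property of the procedure at
this cohort size, not an artifact of the simulator; the default pipeline
configuration (true AUC 0.91 against claims of 0.82/0.82/0.82) passes on
most seeds and fails on a substantial minority, which is faithful to how
such a program behaves across repeated calibration rounds.

### Technical monitoring

Defects: group A = no AI output; group B = the model analyzed only 1–3 of
the 4 standard views (CC and MLO per breast). Monthly level per group is
100 · D/S over the month's submitted flow; months with no flow are absent,
not zero-filled. Window averages are arithmetic means across months. The
trend is ordinary least squares of level on month index, fitted to the
per-month average of the two group levels (per-group trends are also
emitted). In y = ax + b, a is the slope and b the intercept. The alert
comparison is level ≥ threshold (default 10%), because the pass criterion
is strictly "less than 10% of the monthly study flow" — the fail-safe
reading of the boundary. The threshold is applied per group, and the
combined level is reported alongside.

### Clinical monitoring

Each reviewed study receives one rubric category with a fixed
(localization, interpretation) score pair: agreement (1, 1), incorrect
assessment (0.5, 0.5), false positive (0.25, 0.25), false negative (0, 0).
By default the two axes are coupled through the single category; a caller
can supply decoupled per-axis scores in the reviews table and they are used
as-is. The monthly clinical assessment score is 100 · (L̄ + Ī)/2 with both
means arithmetic. Monthly review sets are simple random samples without
replacement under a configurable schedule, defaulting to 20 studies/month
for months 1–10 and 80/month for months 11–22 (1160 reviews total); each
month draws from an independent, seed-derived substream.

### Feedback and conformance

Agree/disagree percentages are reported to one decimal with
largest-remainder reconciliation so the pair always sums to 100.0. The
functional and diagnostic requirement checklists are versioned YAML data
(item id, text, predicate), not hard-coded logic, since requirement
documents evolve; predicates resolve against a declared output descriptor
whose flags are tri-state (yes/no/unknown). A failing item fails the
overall verdict; an unknown flag can at best yield "unknown", never "pass".
Mask rendering is its own predicate: color-only masks fail the visibility
item because they are hard to distinguish on monochrome mammography
monitors.

## Synthetic-data generator

The generator emulates the data a monitoring program actually sees, with
controllable truth:

* **Scores.** Equal-variance binormal latent model: class-conditional
  latent draws N(μ₊, σ) / N(μ₋, σ) mapped through the logistic function.
  AUC is invariant under strictly increasing transforms, so the theoretical
  AUC is Φ((μ₊ − μ₋)/(σ√2)) exactly, and `separation_for_auc` inverts it.
  The latent draw is the study score; the affected breast carries it and
  the contralateral breast receives an independent uniform value below it,
  so `study_score = max(score_left, score_right)` holds by construction
  without disturbing the closed form. (How a per-study probability should
  be derived from two per-breast scores is genuinely underdetermined; the
  maximum is the conservative screening choice.)
* **Class balance and BI-RADS.** Calibration-style cohorts default to
  50/50 over 100 studies; monitoring cohorts default to 10% prevalence,
  the approximate positive share of a large urban screening stream.
  BI-RADS categories are drawn conditional on class with weights taken
  from that stream's composition.
* **Defects.** One uniform draw per study assigns group A with probability
  `rate_no_output`, else group B with probability `rate_partial` (rates sum
  ≤ 1; A takes precedence as "no output" subsumes "partial output").
  Group B draws 1–3 analyzed images uniformly. Defaults for monitoring
  runs decline linearly over the window from A 1.4% / B 7.6% (combined
  9.0%, group B dominant, A matching the share of never-processed studies
  in the emulated stream) to A 0.2% / B 0.8% (combined 1.0%).
* **Reviews.** The rubric category is driven by the study's confusion cell
  at the operating threshold; a true positive is downgraded to "incorrect
  assessment" with probability `p_incorrect` (default 0.25, a realistic
  partial-detection rate chosen once — expert review data give no
  per-category distribution to estimate it from).
* **Feedback.** Bernoulli agree/disagree at `p_agree` (default 0.792)
  attributed uniformly to a pool of 33 end users.

What the generator does **not** model: images and DICOM objects,
equipment- or facility-specific defect clustering, reviewer drift and
replacement effects, correlation between defects and scores, and
case-difficulty structure beyond the binormal family. Passing tests
therefore demonstrate that the evaluation machinery is correct and
reproducible, not that any particular real model meets the criteria.

## Determinism and numerical choices

All randomness flows from a single root seed through
`numpy.random.SeedSequence` stream splitting (one substream per stage);
identical configuration and seed give byte-identical CSV tables and
reports. Rounding for display is half-away-from-zero. The Youden maximum
uses a 1e-12 tie tolerance to absorb floating-point noise in TPR−FPR.
Degenerate inputs raise (`ValueError`) rather than returning sentinel
numbers: single-class ROC input, empty review/feedback sets, fewer than
two distinct months for a trend, zero claimed value in a relative
difference.

Problem sizes in the test suite and acceptance script are chosen to make
Monte-Carlo error negligible relative to each check's tolerance: 2 × 2000
studies for AUC-recovery checks (Hanley–McNeil SE ≈ 0.004), 10⁴ studies
for rate-convergence checks, 50 replicate cohorts for the mean calibration
AUC, and a 22 × 27,346-study stream — the emulated program's own scale —
for the defect-decline trend.

## Known limitations

* No confidence intervals on the calibration metrics and no formal AUC
  comparison test (the pass criterion is a point threshold by design).
* Smoothed/parametric ROC fitting is out of scope; the curve is the
  empirical step function.
* The clinical assessment score inherits the subjectivity of its rubric;
  simulated scores track the configured review-behavior parameters, not
  any particular expert's standard, so absolute simulated score levels are
  not comparable to a real program's.
* One rubric category per study is enforced; real reviews could in
  principle mix, e.g., an incorrect assessment with an additional false
  positive.
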