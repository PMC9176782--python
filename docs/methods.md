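# Methods

## Case-finding model

A pathology record is a set of SNOMED morphology codes, a set of topography
codes, and free text. The case definition is a boolean expression over two
atom kinds, evaluated per record:

* **code atoms** — a literal (`M-81403`) or prefix (`T-2*`) against one
  axis; an atom fires if *any* code of that axis matches;
* **keyword atoms** — searched in the diagnosis field only. `*core*` is a
  substring match, `core*` matches any token beginning with the core
  (token-anchored, so `POLM*` fires on "polmonare" mid-sentence but not on
  "ampolmonare"), a bare core requires token equality. Text and keyword
  cores are case-folded, diacritic-stripped (NFKD, combining marks
  removed) and whitespace-collapsed before matching; tokens are maximal
  `\w+` runs.

Named components combine atoms with AND/OR/NOT; algorithm versions combine
components. The shipped rule set defines the NSCLC inclusion intersection
(histology × chest topography) and three versions that differ in their
exclusions (neuroendocrine morphology; upper-airway topography; optionally
respiratory-NOS topography). Exclusions use **any-match semantics**: one
excluded code on a record vetoes it even when an included code co-occurs.
This is the conservative reading where the source semantics are ambiguous;
it yields the strict nesting `first_modification ⊆ second_modification ⊆
first_version`, which the suite asserts as an invariant. Rule sets are
YAML documents, validated at load with error locations, so the algorithm
is data rather than code.

Keyword search deliberately covers the diagnosis field alone; macroscopy,
microscopy, clinical information and sent material are reserved for manual
review. There is no negation detection or stemming beyond the wildcards —
the definition is meant to be auditable, not linguistically clever.

## Cohorts

Residency filtering happens before evaluation (registry extracts are
linked to an inhabitant registry; non-residents cannot be followed and are
excluded). A patient's case status comes from their earliest matching
record within the closed study window; same-day ties break on the
lexicographically smallest record id so cohorts are order-invariant and
reproducible. The incidence year is the index record's year.

## Validity statistics

**Confirmation rule.** A reviewed case is confirmed iff malignancy, lung
site and NSCLC morphology are all "yes" and primary origin is "yes" or
"maybe" — pathology reports frequently cannot establish origin, so
uncertainty there does not block confirmation. Two blinded raters fill the
form; item-wise disagreements fall to a referee.

**Proportions.** PPV (confirmed/flagged) and the treatment-based SE
indicator (flagged ∩ treated / treated, patient-level) are binomial
proportions with Wilson score 95% intervals (`statsmodels`), labeled in
the estimate's `method` field. Wilson is used for its coverage at moderate
n; the interval construction is a package choice.

**Indirect sensitivity.** When case-level truth is unavailable but
aggregate incidence is, `SE = PPV × P / Π` with P the flagged incidence
and Π the true incidence. Π is modeled as f × L where L is the overall
lung-cancer incidence from a cancer registry and f the NSCLC share;
evaluating at f = 0.80 and f = 0.90 brackets the unknown share, so
se_min/se_max = 8/9 identically. Π is held constant over calendar time at
the reference-year value (a stated assumption, overridable by supplying a
per-year series); estimates above 1 indicate inconsistent inputs and are
capped with a warning. The identity is exact whenever P, PPV and Π derive
from one population: PPV·P/Π = (TP/(TP+FP))·((TP+FP)/N)/((TP+FN)/N) =
TP/(TP+FN); the suite asserts this to 1e-12 relative tolerance. The CI
treats the flagged count as binomial over the population and transforms
its Wilson interval through the identity with PPV and Π held fixed — an
approximation that ignores PPV sampling error, labeled as such.

**Kappa.** Unweighted Cohen's κ from the raters' contingency table,
κ = (p_o − p_e)/(1 − p_e), with Landis–Koch bands (≤0 poor, ≤0.20 slight,
≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, else almost perfect). When
both raters are constant and identical, p_e = 1 and κ is undefined (None,
with a warning) rather than 1. Only doubly-rated records enter; singly
rated ones are dropped with a logged count. Note that among flagged
records the malignancy item is nearly constant ("yes"), so its κ is
legitimately near zero despite high raw agreement — low marginal variance,
not rater failure.

## Synthetic registry

The generator emulates a regional registry world: each patient draws a
true class (primary NSCLC 25%, neuroendocrine lung 3%, upper-airway cancer
5%, other-site cancer 42%, lung metastasis 1.2%, benign 23.8%), a
diagnosis year uniform over 2009–2017, and residency (87%). Captured
patients emit one record (20% a duplicate follow-up with identical
content) whose codes and Italian diagnosis text come from a
class-conditional emission model:

* NSCLC morphology: specific listed code with probability 0.85, else a
  generic `M-8*` code (70% of the remainder) whose text carries a
  histology keyword with probability 0.8, else a miscode outside `M-8*`;
* NSCLC topography: specific lung code (0.92), respiratory-NOS `T-20000`
  (0.03), or no code, with a lung keyword emitted at 0.8;
* non-lung cancers carry their own codes and mention the lung in text
  (suspected pulmonary metastasis) with probability 0.0165 — the realistic
  false-positive channel; lung metastases code as lung adenocarcinoma and
  are the irreducible false positives that only the origin item catches.

Registry capture of a true case's record rises linearly 0.20 → 0.70 over
2009–2017, emulating a young registry whose completeness grows; the 10% of
NSCLC cases treated at the hospital pharmacy are captured at 0.85
regardless of year, which is why the treatment-based SE indicator (~0.79
expected) sits far above the population sensitivity. Three independent
random streams (records, treatments, raters) spawn from the master seed,
so adding raters never perturbs record generation.

Because every choice above is an independent finite draw,
`expected_validity` enumerates the outcome space exactly: flag probability
per class per version, expected PPV = P(primary NSCLC | flagged), expected
SE(year) = P(flagged | primary NSCLC, year), and the expected
*review-based* PPV, which additionally folds in the exact probability that
an adjudicated review confirms each class under the rater-error model
(per item, a wrong adjudicated level requires both raters to deviate to
the same wrong level; the referee is error-free). The review-based form is
the correct yardstick for the pipeline's empirical PPV, which uses
adjudicated reviews — not truth — as its reference standard; at the
default 5% rater error the two differ by ~0.4 percentage points.

Defaults (shipped as `paperlike.params`) were calibrated once so the
closed-form expected PPV of the final version is ≈0.93 and expected SE
rises ≈0.25 → ≈0.65 across the period; parameter-recovery tests then
compare empirical estimates at n = 50,000 against the closed form within
Monte-Carlo sampling bands, and assert the qualitative trend (year-wise
monotone non-decreasing sensitivity).

**What the generator does not model.** Realistic clinical prose beyond
keyword-bearing templates; tumour stage, treatment lines, survival;
within-patient histology changes; correlated rater errors; migration or
year-varying population. Passing tests therefore demonstrate internal
consistency of the statistical machinery and the rule engine under
controlled misclassification — not the external validity of the rule set
on any real registry, which requires local manual review. Counts that are
properties of the actual source registries (numbers of retrieved or
linkable records, region-wide case totals, observed kappa values) are
emulated in scale only, never reproduced.

## Numerical choices and degenerate inputs

* Wilson bounds are clamped to contain the point estimate (floating noise
  at 0/n counts).
* Zero denominators raise; zero flagged cases in a year yield an SE range
  of [0, 0] rather than an error.
* Same-day cohort ties break deterministically (record id).
* Keyword patterns with a leading `*` but no trailing `*` are rejected as
  malformed rather than silently treated as exact.
* Problem sizes in the suite: rule-engine oracle equivalence on 1,000
  adversarial fuzz records; parameter recovery on the 50,000-patient
  default world; kappa and indirect-SE oracles on 100 random instances.
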