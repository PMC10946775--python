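# Methods

## Setting and data model

The package operates on three delimited-text tables typical of UK
primary-care research extracts: children (id, date of birth, end of
follow-up), coded events (dated CTV3-style diagnosis codes with their term
text) and prescriptions (dated issues with BNF-style product codes).
Prescription products are mapped to ten medication classes —
bronchodilators, inhaled corticosteroids, leukotriene receptor
antagonists, topical corticosteroids, emollients, topical calcineurin
inhibitors, systemic corticosteroids, immunoregulators, antihistamines and
intranasal corticosteroids — by longest-prefix match on the BNF code, so a
map can be specified at chapter, section or product granularity.

Validation is row-level and audited: a row with an unparseable date, an
unknown child id, a date outside the child's [dob, follow-up] interval or
an unmappable BNF code goes to a rejects report
(`source_file,row_number,reason`) rather than being silently dropped.
Structural faults (missing columns) abort the load. Diagnosis codes are
opaque and case-sensitive; only term *text* is matched case-insensitively.

## Calendar conventions

All age thresholds use completed years; the birthday itself counts (age
increments on the anniversary). "Age 3–5 years" therefore means completed
age ∈ {3,4,5}. Feb-29 birthdays anniversary on 1 March in non-leap years —
a deterministic, testable convention. "Per year" prescription counts use
age-years ([k-th birthday, (k+1)-th birthday)), anchoring to the age
phrasing of the rules; calendar years would misalign with age. The hay
fever season is 1 March–31 July inclusive at both ends, in any year.

## The case definitions

Six classifiers, two per outcome (see README for the table). Decisions
taken where the prose leaves room, each exposed as an explicit flag or
documented convention:

* **Asthma, prescription arm.** "Bronchodilators or inhaled
  corticosteroids or leukotriene receptor antagonists" is read as a class
  union: the three classes pool towards the ≥ 3-per-age-year threshold.
  A strict per-class mode (`RuleFlags(pool_asthma_classes=False)`) keeps
  the alternative reading available. The qualifying age-year may precede
  the age-3–5 code and need not be fully observed; the rules are silent
  and the least-assumption default avoids discarding children with short
  records. An optional minimum-follow-up filter
  (`filter_min_followup_age`) exists, off by default.
* **Eczema.** Codes before the first birthday are ignored entirely —
  including for anchoring: the prescription window [D − 90 d, D + 365 d]
  hangs off the first code *at age ≥ 1*, with both endpoints inclusive.
  Two same-day items count as two prescriptions (items are the table's
  unit; no de-duplication rule exists). A consequence worth knowing: the
  first definition is not monotone under adding an *earlier* eligible
  code, because that re-anchors the window. The monotonicity tests assert
  the property for all other additions and document this exception.
* **Rhinitis.** The first definition is code-only; the *second* is the
  more specific one (the naming deliberately reverses the asthma/eczema
  pattern). By default the seasonal code and the seasonal prescription may
  fall in different calendar years — "during at least one hay fever
  season" binds each clause separately; `RuleFlags(rhinitis_same_year=True)`
  enforces the strict same-year reading.

Every positive classification carries machine-readable evidence (rule
branch plus triggering dates), so any case can be audited back to records.

## Codelist construction

Outcome codelists are built from two sources: published code sets, and
case-insensitive substring mining of the term text in a local code
dictionary (regex only behind a flag — substring is the reproducible
minimum). Candidates matching an exclusion pattern (screening invites,
family history, vague terms) are *retained* with `decision=exclude` and
the matching pattern as reason; exclusion beats inclusion, both within
mining and when merging lists, mirroring a manual veto that should survive
any union. The final human shortlisting step cannot be automated; it is
represented as the editable decision column of the exported CSV.

## Concordance (PPV/NPV)

Prescription exposure per class follows the outcome-specific criteria:
asthma ≥ 3 items in ≥ 1 age-year from age 6 (the same machinery as the
case definition); eczema ≥ 2 items at completed age 0–7; rhinitis ≥ 1
in-season item at completed age 0–6. The pooled "any of the above" row is
the per-child OR of component-class statuses. Code-only status applies the
outcome's age restriction (asthma ≥ 3, eczema ≥ 1, rhinitis any age), i.e.
the code-only definition of each outcome.

Confidence intervals default to Clopper–Pearson (via
`statsmodels.stats.proportion.proportion_confint`, method `beta`), chosen
because it behaves at the boundaries — at x = n the interval is
(0.025^(1/n), 1) where the Wald interval collapses to a point. Wilson and
Wald are provided; published tables of this kind do not always state their
interval method and are not always internally consistent with a single
one, so only the boundary case identifies the method. Report formatting is
round-half-up: proportions to 2 decimals, column percentages to 1.
Undefined proportions (empty denominator) raise a distinct signal and
render as blank cells, never as 0.

## Synthetic cohorts

`generate_cohort` draws: uniform dates of birth over 2007-03-01 to
2010-12-31 with 11 years of follow-up and n = 13,044 by default (the scale
of a fully-linked UK birth cohort); per outcome, Bernoulli code-positivity
and a log-normal age at first code truncated to a plausible range (eczema
median 2 y on ages 1–6, asthma median 5 y on 3–10.5, rhinitis median 5 y);
per medication class, a Poisson item count whose rate depends on the
child's code status for the class's outcome. Items are placed inside the
criterion-relevant window (asthma: the age-6 year; eczema: the first-code
window for code-positive children, ages 0–7 otherwise; rhinitis: hay-fever
seasons at ages 0–6), so the count that the exposure criterion sees *is*
the Poisson draw and every 2×2 cell probability has the closed form
prevalence × P(Poisson(λ) ≥ threshold | status). That closed form is the
oracle for the parameter-recovery tests.

Default rates are solved (deterministic root-finding on the Poisson tail
at config construction) so that P(criterion met | code status) equals the
concordance fractions observed in linked UK primary-care records for these
outcomes — e.g. emollients are near-universal regardless of code status
while inhaled corticosteroids are rare without a code. Probabilities are
clipped to ≤ 0.999 before inversion (a conditional probability of exactly
1, as for emollients among coded children, has no finite rate).

What the generator does **not** emulate: consultation-level structure,
repeat-prescribing patterns, multiple codes per child per outcome,
comorbidity correlation between outcomes, GP-practice clustering, and
calendar trends. Passing tests therefore show the *rules and statistics*
are implemented correctly under the assumed structure, not that the
definitions are clinically valid in real data.

`generate_exact_fixture` instead builds one minimal child per 2×2 cell
(e.g. asthma cell a: one code 30 days after the 6th birthday plus three
same-class items inside the age-6 year), so published cell counts are
reproduced bit-exactly through the full load → status → cross-tabulation
pipeline; minimality keeps every child hand-checkable.

## Problem sizes and numerics

The test suite exercises: brute-force oracle equivalence on 1,000+ random
≤ 10-child cohorts (the oracle is an independent day-counting, nested-loop
re-implementation of the prose); exact-interval agreement with direct
bisection inversion of the binomial tails; interval coverage at n = 50,
p = 0.5 over 2,000 replicates; parameter recovery at n = 10,000 within 3
binomial standard errors per cell; and full-pipeline fixture reproduction
at n = 13,044. Monte-Carlo diagnostics in `recover_parameters` report
binomial standard errors per cell. All simulation entry points take a
single integer seed (numpy `default_rng`); identical config + seed gives
byte-identical tables.

## Known limitations

* The shipped codelists and BNF class map are small synthetic stand-ins
  for reviewed clinical lists; real analyses must supply their own.
* PPV/NPV here treat codes as the reference standard; without an external
  gold standard no sensitivity/specificity can be computed, and a low PPV
  may reflect over-the-counter availability rather than miscoding.
* The classifiers are deterministic rules; no probabilistic phenotyping,
  free-text NLP or severity grading is attempted.
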