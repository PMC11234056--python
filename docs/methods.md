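# Methods

## What the package models

`ebmkit` represents units of biomedical evidence as the FHIR-style resource
set used for evidence exchange: **Evidence** (variable definitions by role,
statistics, certainty ratings), **EvidenceVariable**, **Group**,
**Citation**, and **ArtifactAssessment**. The supported element set is the
evidence-exchange subset, not full FHIR: each resource models the elements
needed to carry a statistical finding, its variables, its certainty, and its
attribution. Anything outside that subset is handled by the I/O layer's
retention policy (kept verbatim and re-emitted, never interpreted), so the
package can round-trip documents produced by richer implementations without
pretending to understand them. `EvidenceReport`/`Composition` containers and
implementation-guide profiles are out of scope.

Validation is issue-based: `validate_resource` returns a list of
`(severity, path, message)` records rather than raising, so a caller sees
every problem at once. Structural invariants (cardinalities such as the
required `variableDefinition`, at most one population role, count ordering
like `numberOfEvents <= knownDataCount`, interval ordering, certainty
nesting depth of two) are errors in both modes; terminology bindings
(statistic type against the packaged 22-code value set, certainty aspects
against the nine-aspect list, variable roles against the six-role list) are
errors in `strict` mode and warnings in `lenient` mode. The element names
(`variableDefinition`, `statisticType`, `attributeEstimate`, `certainty`,
the `value[x]` choice convention) are pinned to the FHIR 6.0 build this
model follows; later upstream renames are deliberately not tracked, because
a stable serialization contract matters more here than chasing the
specification head.

### Serialization choices

JSON only, UTF-8; bundles are newline-delimited JSON. Canonical writing puts
`resourceType` first, uses a fixed key order, and is byte-deterministic, so
equality of canonical text is a usable identity test. Decimal values pass
through Python floats whose shortest-repr round-trip preserves the printed
digits (1.27 stays `1.27`); no re-rounding is applied. `variableRole` is
serialized as a plain code (the 6.0-build shape); a CodeableConcept-shaped
role is accepted on input for compatibility. Element paths use dotted names
with 0-based bracketed indices (`statistic[0].attributeEstimate[1].level`).

## Terminologies

Code systems are concept lists with an optional single-parent hierarchy
(checked acyclic at load); value sets compose `all`, `listed-codes`, and
`descendants-of` includes, with `descendants-of` computed by breadth-first
search over the child map and the root excluded unless requested. Expansion
deduplicates and sorts by (system, code), making it idempotent and
order-deterministic.

The packaged registry ships:

* **statistic-type** — a 22-code value set of summary/effect measures.
  Only three exemplars (median, relative risk, incidence rate ratio) were
  externally fixed; the remaining 19 are the implementation's choice of
  standard measures (mean, odds ratio, hazard ratio, risk difference,
  standardized mean difference, C-statistic, ...).
* **certainty-aspect** — the nine GRADE-style aspects (overall certainty,
  risk of bias, inconsistency, indirectness, imprecision, publication bias,
  dose-response gradient, plausible confounding, large effect size).
* **certainty-rating** — high / moderate / low / very-low, plus a small
  modifier system (no-concern, serious-concern, ...) for aspect-level
  judgments.
* **variable-role** — population, subpopulation, exposure,
  reference-exposure, measured-variable, confounder.
* **attribute-estimate-type** and **statistical-model** support systems.
* **study-design** and **risk-of-bias** — small representative stubs; the
  full controlled vocabularies for those domains run to hundreds of terms
  and are not reconstructed here.

System URIs are project-local URNs (`urn:ebmkit:codesystem:*`) so that no
HL7/SEVCO URI is impersonated; user-supplied systems load from the same
JSON shape.

## Effect statistics

For a 2x2 table with exposed-arm cells (a events, b non-events) and
reference-arm cells (c, d):

* odds ratio `(a d)/(b c)`, log-scale SE `sqrt(1/a + 1/b + 1/c + 1/d)`
  (Woolf);
* risk ratio `(a/n1)/(c/n2)`, log-scale SE
  `sqrt(1/a - 1/n1 + 1/c - 1/n2)`;
* risk difference with the plain-scale binomial SE;
* proportions with Wilson score intervals (delegated to
  `statsmodels.stats.proportion.proportion_confint`).

Interval construction uses the standard normal quantile (1.959964 for 95%).
A 0.5 continuity correction is added to all four cells only when some cell
is zero (`continuity=False` disables it); tables with both cells of one
margin zero raise `UndefinedMeasureError` rather than returning a number.
Percentages render half-up to one decimal (`Decimal` arithmetic, so
0.764313... prints 76.4%).

`to_statistic` writes an estimate into a `Statistic` with a coded statistic
type, the interval as an `AttributeEstimate` (level + range), and the SE as
a second attribute estimate; `statistic_to_estimate` inverts it, preferring
the explicit SE and otherwise recovering it from the interval width on the
analysis scale (log for ratios). The credible-vs-confidence distinction is
carried only in the interval's type coding; reported Bayesian results (such
as an adjusted odds ratio from a covariate-adjusted ordinal model) are
stored as data with `bayesian`/`covariate-adjusted` model characteristics,
never recomputed.

## Evidence synthesis

Two Evidence resources are comparable when, role by role, their variable
definitions resolve to the same concept-key sets. Keys are
`(system, code)` pairs from codings; display text is ignored; a variable
defined only by text contributes a case- and whitespace-normalized text key.
Coded concepts take precedence — text keys are used only when a variable
carries no codings — and two text-only definitions match only on exact
normalized equality, a deliberately conservative rule. Matching uses the
`intended` reference when present, else `observed`; `require_both=True`
demands they agree.

Pooling is inverse-variance on the analysis scale. Fixed-effect weights are
`1/v_i`; the random-effects model uses the DerSimonian–Laird moment
estimator `tau^2 = max(0, (Q - df)/(S1 - S2/S1))` with re-weighting
`1/(v_i + tau^2)`. Heterogeneity is summarized by Cochran's Q and
`I^2 = max(0, (Q - df)/Q)`. DL was chosen because it is the field's default
moment estimator and closed-form (REML would be a reasonable future
option). A pooled result can be re-emitted as an Evidence resource carrying
`numberOfStudies = k`, the pooling-model characteristic (plus tau^2 for
random effects), and attribute estimates for the CI, Q, and I^2 — the
output validates strictly, closing the loop.

Known behavior worth stating: with k around 10 and moderate heterogeneity
the DL interval is anti-conservative — measured coverage of a nominal 95%
interval under this package's generative model is about 92%, consistent
with the literature on the estimator. The acceptance measurement reports
the observed coverage rather than hiding it.

## Synthetic data

`simulate_evidence_set` draws, per study, a log odds ratio from
Normal(`true_log_effect`, `tau^2`), uniform arm sizes, reference-arm events
Binomial(n, `baseline_risk`), and exposed-arm events from the baseline odds
multiplied by the study OR. Defaults — k = 10 studies, arm sizes 100–500,
baseline risk 0.30, true OR 1.27 (the walkthrough effect size), tau = 0.2 —
describe a moderately sized body of two-arm trials with realistic
between-study spread. The binomial-logit model was chosen because the
synthesis module pools log-ORs: matched scales make parameter recovery a
clean end-to-end check. One explicit seed drives every draw, so generation
is fully reproducible.

What the generator does **not** emulate: ordinal or time-to-event outcomes,
covariate adjustment, missing data, unequal allocation, publication bias,
or correlated multi-arm structures. Passing tests therefore demonstrate the
machinery's correctness on clean dichotomous two-arm data, not robustness
to the messiness of real evidence bases.

## Bibliographic conversion

RIS records are `TY`...`ER` delimited; MEDLINE/nbib records begin at `PMID`
with leading-whitespace continuation lines joined by a single space. The
tag maps are fixed tables (`RIS_TAG_MAP`, `MEDLINE_TAG_MAP`); journal-name
dialects resolve by priority (RIS: JO > JF > T2; MEDLINE: TA > JT) and the
superseded sibling, like every unmapped tag, is retained as a classifier
annotation on the Citation, so conversion is lossless up to the documented
map. Author order is preserved into contributor order. Dates accept
year-only values; no locale inference is attempted. A record with neither a
title nor an identifier cannot become a Citation and raises.

## Problem sizes used in checks

The packaged measurements run at desk scale: the eight-resource walkthrough
bundle; 100 random 5-study blocks against an explicit-sums pooling oracle
(agreement within 1e-10); 500 seeded replicates for interval coverage;
about 110 resources for JSON round-trip identity; 20 random 50-node
hierarchies for expansion-vs-reachability; 200 random tables for arm-swap
reciprocity (within 1e-12). These sizes give Monte-Carlo error well below
the tolerances being checked while keeping the whole suite under a few
seconds.

## Limitations

* No network meta-analysis, meta-regression, or publication-bias tests
  (the aspect codes exist in the terminology; the computations do not).
* No XML or RDF serializations; no FHIR REST client/server.
* The study-design and risk-of-bias systems are stubs, not the full
  controlled vocabularies.
* Adjusted/Bayesian estimates are stored, never re-derived.
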