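# ebmkit

Computable evidence-based medicine for Python: model, validate, serialize,
and render FHIR-style evidence resources; compute effect statistics from
count data and express them inside those resources; pool comparable
evidence by inverse-variance meta-analysis; manage the controlled
terminologies the resources bind to; and convert RIS / MEDLINE
bibliographic records into Citation resources.

It is aimed at people who build or consume machine-readable evidence —
systematic reviewers, guideline and decision-support developers,
informaticians wiring trial results into downstream tools — and who need
study findings as structured, validatable JSON rather than prose.

## The core model

A unit of evidence is an **Evidence** resource: variable definitions by
role (population, exposure, reference exposure, measured variable, ...),
each resolving to an **EvidenceVariable** or **Group** resource; one or
more **Statistic** structures (quantity, coded statistic type, sample
size, attribute estimates such as confidence/credible intervals, P values
and heterogeneity estimates, and statistical-model characteristics); and
GRADE-style certainty ratings over nine aspects. **Citation** and
**ArtifactAssessment** resources carry attribution and appraisal.

On the statistical side, for a 2x2 table (a, b; c, d):

- odds ratio  OR = ad / bc,  SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d)
- risk ratio  RR = (a/n1) / (c/n2),  SE(log RR) = sqrt(1/a − 1/n1 + 1/c − 1/n2)
- proportions use Wilson score intervals

and inverse-variance pooling of k studies on the log scale, with the
DerSimonian–Laird estimator for between-study variance:

    Q = Σ wᵢ(θᵢ − θ̂_FE)²,   τ² = max(0, (Q − df) / (S₁ − S₂/S₁)),
    I² = max(0, (Q − df)/Q),  w*ᵢ = 1/(vᵢ + τ²)

Comparable studies are found automatically by matching
`variableDefinition` content (coded concepts first, normalized text as a
fallback). See `docs/methods.md` for assumptions and numerical choices.

## Worked example

The package ships a programmatic fixture: an eight-resource bundle
describing the primary outcome of a multiplatform randomized trial of
therapeutic-dose anticoagulation in hospitalized noncritically ill
COVID-19 patients.

```python
import ebmkit as e

bundle = e.build_walkthrough()          # 2 Citations, 1 Evidence,
                                        # 3 EvidenceVariables, 2 Groups
assert all(e.validate_resource(r) == [] for r in bundle.resources)
print(e.render(bundle.evidence[0]).text)
```

```
Evidence walkthrough-evidence: Effect of therapeutic-dose anticoagulation on organ support-free days in hospitalized noncritically ill COVID-19 patients
  exposure (therapeutic-dose anticoagulation) -> EvidenceVariable/walkthrough-variable-intervention
  reference-exposure (usual-care thromboprophylaxis) -> EvidenceVariable/walkthrough-variable-comparator
  measured-variable (organ support-free days) -> EvidenceVariable/walkthrough-variable-outcome
  odds ratio 1.27 (95% credible interval 1.03–1.58)
    median adjusted odds ratio for improvement in organ support-free days (therapeutic-dose anticoagulation vs usual-care thromboprophylaxis)
  certainty (overall certainty): Moderate
    certainty (risk of bias): serious concern
```

The 1.27 (1.03–1.58) is the trial's reported median adjusted odds ratio
with its 95% credible interval, stored as data in the Statistic. The arm
Groups carry the raw counts, rendered with the derived percentages:

```python
print(e.render(bundle.groups[0]).text)
```

```
Group walkthrough-group-intervention: therapeutic-dose anticoagulation arm
  members: 1171
  received therapeutic-dose anticoagulation with heparin
  participants with the primary-outcome event: 939/1171 (80.2%)
```

Computing and pooling from scratch:

```python
counts = e.TwoByTwoCounts(939, 232, 801, 247)
est = e.compute_odds_ratio(counts)      # unadjusted OR 1.2481 (1.0193–1.5282)

sim = e.simulate_evidence_set(e.SimulationConfig(k=4, seed=5))
from ebmkit.io import Resolver
evidence = [r for r in sim if isinstance(r, e.EvidenceResource)]
block = e.group_comparable(evidence, Resolver(sim))[0]
result = e.pool([e.statistic_to_estimate(ev.statistic[0]) for ev in block],
                model="random")
```

The same operations are available from the shell:

```bash
ebmkit fixture walkthrough --out walkthrough.ndjson
ebmkit validate walkthrough.ndjson       # exit 0, "all resources valid"
ebmkit stats -a 939 -b 232 -c 801 -d 247 --format text
#   odds-ratio 1.24808 (95% CI 1.01931–1.52819)
ebmkit fixture simulate --k 4 --seed 5 --out sim.ndjson
ebmkit meta sim.ndjson --model random --format text
ebmkit convert refs.ris --from ris       # RIS -> Citation ndjson
ebmkit render walkthrough.ndjson
```

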