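"""Programmatic fixtures: the anticoagulation-trial walkthrough bundle and
a seeded generator of synthetic evidence sets.

``build_walkthrough`` reconstructs, entirely in code, the eight-resource
set describing the primary outcome of a multiplatform randomized trial of
therapeutic-dose anticoagulation in hospitalized noncritically ill
COVID-19 patients: two Citations, one Evidence, three EvidenceVariables,
and two Groups (the trial arms).  The Evidence statistic stores the
trial's reported median adjusted odds ratio 1.27 with its 95% credible
interval 1.03-1.58 (the Bayesian ordinal model behind it is reported
data, not recomputed here); the arm Groups carry 939/1171 and 801/1048
participants with the primary-outcome event.

``simulate_evidence_set`` draws per-study log odds ratios from
Normal(true_log_effect, tau^2), binomial arm counts, and emits one
Evidence resource per study over a shared set of variables -- a
generative model matched to the log-OR scale the synthesis module pools
on, so parameter recovery is directly checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import model as m
from .statistics import TwoByTwoCounts, compute_odds_ratio, to_statistic
from .terminology import SYSTEM_URI

__all__ = [
    "WalkthroughBundle",
    "SimulationConfig",
    "build_walkthrough",
    "simulate_evidence_set",
]

_ST = SYSTEM_URI["statistic-type"]
_CA = SYSTEM_URI["certainty-aspect"]
_CR = SYSTEM_URI["certainty-rating"]
_CM = SYSTEM_URI["certainty-modifier"]
_AE = SYSTEM_URI["attribute-estimate-type"]
_SM = SYSTEM_URI["statistical-model"]
_EX = "urn:ebmkit:codesystem:example"

#: Trial arm counts: (participants, participants with the primary-outcome event).
WALKTHROUGH_COUNTS = {
    "intervention": (1171, 939),
    "comparator": (1048, 801),
}

#: Reported primary result: median adjusted OR and 95% credible interval.
WALKTHROUGH_OR = 1.27
WALKTHROUGH_CRI = (1.03, 1.58)

OUTCOME_DESCRIPTION = (
    "organ support–free days, evaluated on an ordinal scale that combined "
    "in-hospital death and the number of days free of cardiovascular or "
    "respiratory organ support up to day 21 among patients who survived to "
    "hospital discharge"
)


@dataclass
class WalkthroughBundle:
    """The eight-resource walkthrough set with typed accessors."""

    citations: list[m.CitationResource] = field(default_factory=list)
    evidence: list[m.EvidenceResource] = field(default_factory=list)
    evidence_variables: list[m.EvidenceVariableResource] = field(default_factory=list)
    groups: list[m.GroupResource] = field(default_factory=list)

    @property
    def resources(self) -> list[m.AnyResource]:
        return [*self.citations, *self.evidence, *self.evidence_variables, *self.groups]


def _cc(system: str, code: str, display: str, text: str | None = None):
    return m.CodeableConcept(
        coding=[m.Coding(system=system, code=code, display=display)], text=text
    )


def _arm_group(arm: str, name: str, description_text: str) -> m.GroupResource:
    total, events = WALKTHROUGH_COUNTS[arm]
    return m.GroupResource(
        id=f"walkthrough-group-{arm}",
        name=name,
        member_count=total,
        characteristics=[
            m.GroupCharacteristic(
                code=_cc(_EX, f"{arm}-exposure", description_text),
            ),
            m.GroupCharacteristic(
                code=_cc(
                    _ST,
                    "count",
                    "count",
                    text="participants with the primary-outcome event",
                ),
                value=m.Quantity(value=events, unit="participants"),
            ),
        ],
    )


def build_walkthrough() -> WalkthroughBundle:
    """Construct the walkthrough bundle; deterministic on every call."""
    citation_article = m.CitationResource(
        id="walkthrough-citation-article",
        summary=(
            "Therapeutic anticoagulation with heparin in noncritically ill "
            "patients with Covid-19. N Engl J Med. 2021;385(9):790-802."
        ),
        cited_artifact=m.CitedArtifact(
            identifiers=[
                m.Identifier(type="doi", value="10.1056/NEJMoa2105911"),
                m.Identifier(type="pmid", value="34351721"),
            ],
            title=(
                "Therapeutic anticoagulation with heparin in noncritically "
                "ill patients with Covid-19"
            ),
            publication_form=m.PublicationForm(
                published_in_title="New England Journal of Medicine",
                date="2021-08-26",
                volume="385",
                issue="9",
                first_page="790",
                last_page="802",
            ),
            contributorship=[
                m.Contributor(
                    name="ATTACC, ACTIV-4a, and REMAP-CAP Investigators",
                    roles=["author"],
                )
            ],
        ),
    )
    citation_evidence = m.CitationResource(
        id="walkthrough-citation-evidence",
        summary=(
            "Citation for the evidence summary of the trial's primary outcome"
        ),
        cited_artifact=m.CitedArtifact(
            identifiers=[
                m.Identifier(type="local", value="Evidence/walkthrough-evidence")
            ],
            title=(
                "Summary of one unit of evidence (statistical findings for "
                "one set of variables) from the study"
            ),
        ),
    )

    ev_intervention = m.EvidenceVariableResource(
        id="walkthrough-variable-intervention",
        name="therapeutic-dose anticoagulation",
        description="Exposure in the intervention arm of the study",
        definition=_cc(
            _EX,
            "therapeutic-anticoagulation",
            "therapeutic-dose anticoagulation with heparin",
        ),
        handling="dichotomous",
    )
    ev_comparator = m.EvidenceVariableResource(
        id="walkthrough-variable-comparator",
        name="usual-care thromboprophylaxis",
        description="Exposure in the comparator arm of the study",
        definition=_cc(
            _EX,
            "usual-care-thromboprophylaxis",
            "usual-care pharmacologic thromboprophylaxis",
        ),
        handling="dichotomous",
    )
    ev_outcome = m.EvidenceVariableResource(
        id="walkthrough-variable-outcome",
        name="organ support-free days",
        description=OUTCOME_DESCRIPTION,
        definition=_cc(
            _EX, "organ-support-free-days", "organ support-free days",
            text=OUTCOME_DESCRIPTION,
        ),
        handling="ordinal",
    )

    group_intervention = _arm_group(
        "intervention",
        "therapeutic-dose anticoagulation arm",
        "received therapeutic-dose anticoagulation with heparin",
    )
    group_comparator = _arm_group(
        "comparator",
        "usual-care thromboprophylaxis arm",
        "received usual-care pharmacologic thromboprophylaxis",
    )

    n_total = sum(total for total, _ in WALKTHROUGH_COUNTS.values())
    statistic = m.Statistic(
        description=(
            "median adjusted odds ratio for improvement in organ "
            "support-free days (therapeutic-dose anticoagulation vs "
            "usual-care thromboprophylaxis)"
        ),
        statistic_type=_cc(
            _ST, "odds-ratio", "odds ratio", text="median adjusted odds ratio"
        ),
        quantity=m.Quantity(value=WALKTHROUGH_OR),
        sample_size=m.SampleSize(
            total_participants=n_total,
            known_data_count=n_total,
            number_of_studies=1,
        ),
        attribute_estimate=[
            m.AttributeEstimate(
                type=_cc(_AE, "credible-interval", "credible interval"),
                level=0.95,
                range_low=m.Quantity(value=WALKTHROUGH_CRI[0]),
                range_high=m.Quantity(value=WALKTHROUGH_CRI[1]),
            )
        ],
        model_characteristic=[
            m.ModelCharacteristic(code=_cc(_SM, "bayesian", "Bayesian model")),
            m.ModelCharacteristic(
                code=_cc(_SM, "covariate-adjusted", "covariate-adjusted")
            ),
        ],
    )

    evidence = m.EvidenceResource(
        id="walkthrough-evidence",
        title=(
            "Effect of therapeutic-dose anticoagulation on organ "
            "support-free days in hospitalized noncritically ill COVID-19 "
            "patients"
        ),
        description=(
            "Summary of one unit of evidence (statistical findings for one "
            "set of variables) from a multiplatform randomized controlled "
            "trial of anticoagulation for hospitalized noncritically ill "
            "patients with COVID-19"
        ),
        variable_definition=[
            m.VariableDefinition(
                variable_role="exposure",
                description="therapeutic-dose anticoagulation",
                observed=m.Reference(
                    target="Group/walkthrough-group-intervention",
                    resolved_type="Group",
                ),
                intended=m.Reference(
                    target="EvidenceVariable/walkthrough-variable-intervention",
                    resolved_type="EvidenceVariable",
                ),
            ),
            m.VariableDefinition(
                variable_role="reference-exposure",
                description="usual-care thromboprophylaxis",
                observed=m.Reference(
                    target="Group/walkthrough-group-comparator",
                    resolved_type="Group",
                ),
                intended=m.Reference(
                    target="EvidenceVariable/walkthrough-variable-comparator",
                    resolved_type="EvidenceVariable",
                ),
            ),
            m.VariableDefinition(
                variable_role="measured-variable",
                description="organ support-free days",
                observed=m.Reference(
                    target="EvidenceVariable/walkthrough-variable-outcome",
                    resolved_type="EvidenceVariable",
                ),
                intended=m.Reference(
                    target="EvidenceVariable/walkthrough-variable-outcome",
                    resolved_type="EvidenceVariable",
                ),
            ),
        ],
        statistic=[statistic],
        certainty=[
            m.CertaintyRating(
                type=_cc(_CA, "overall-certainty", "overall certainty"),
                rating=_cc(_CR, "moderate", "Moderate"),
                rater="walkthrough appraisal",
                subcomponents=[
                    m.CertaintyRating(
                        type=_cc(_CA, "risk-of-bias", "risk of bias"),
                        rating=_cc(_CM, "serious-concern", "serious concern"),
                    )
                ],
            )
        ],
    )

    return WalkthroughBundle(
        citations=[citation_article, citation_evidence],
        evidence=[evidence],
        evidence_variables=[ev_intervention, ev_comparator, ev_outcome],
        groups=[group_intervention, group_comparator],
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic evidence set.

    Defaults describe a moderately sized body of two-arm trials: ten
    studies of 100-500 participants per arm, a 30% baseline event risk,
    a true odds ratio of about 1.27 (matching the walkthrough effect
    size), and between-study heterogeneity tau = 0.2 on the log-OR scale.
    """

    k: int = 10
    true_log_effect: float = math.log(1.27)
    tau: float = 0.2
    arm_size_range: tuple[int, int] = (100, 500)
    baseline_risk: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0.0 < self.baseline_risk < 1.0):
            raise ValueError("baseline_risk must lie in (0, 1)")
        lo, hi = self.arm_size_range
        if not (0 < lo <= hi):
            raise ValueError("arm_size_range must satisfy 0 < min <= max")


def _shared_variables() -> list[m.AnyResource]:
    return [
        m.EvidenceVariableResource(
            id="sim-variable-exposure",
            name="simulated exposure",
            definition=_cc(_EX, "sim-exposure", "simulated exposure"),
            handling="dichotomous",
        ),
        m.EvidenceVariableResource(
            id="sim-variable-reference",
            name="simulated reference exposure",
            definition=_cc(_EX, "sim-reference", "simulated reference exposure"),
            handling="dichotomous",
        ),
        m.EvidenceVariableResource(
            id="sim-variable-outcome",
            name="simulated outcome",
            definition=_cc(_EX, "sim-outcome", "simulated dichotomous outcome"),
            handling="dichotomous",
        ),
        m.GroupResource(
            id="sim-group-population",
            name="simulated trial population",
            characteristics=[
                m.GroupCharacteristic(
                    code=_cc(_EX, "sim-population", "simulated trial population")
                )
            ],
        ),
    ]


def draw_counts(cfg: SimulationConfig, rng: np.random.Generator) -> TwoByTwoCounts:
    """Draw one study's 2x2 table under the binomial-logit model."""
    theta = rng.normal(cfg.true_log_effect, cfg.tau)
    lo, hi = cfg.arm_size_range
    n1 = int(rng.integers(lo, hi + 1))
    n2 = int(rng.integers(lo, hi + 1))
    p0 = cfg.baseline_risk
    odds1 = p0 / (1 - p0) * math.exp(theta)
    p1 = odds1 / (1 + odds1)
    events_exposed = int(rng.binomial(n1, p1))
    events_reference = int(rng.binomial(n2, p0))
    return TwoByTwoCounts(
        events_exposed=events_exposed,
        nonevents_exposed=n1 - events_exposed,
        events_reference=events_reference,
        nonevents_reference=n2 - events_reference,
    )


def simulate_evidence_set(cfg: SimulationConfig) -> list[m.AnyResource]:
    """Generate a bundle of Evidence resources over shared variables.

    Per study: a study log-OR from Normal(true_log_effect, tau^2), uniform
    arm sizes, binomial event counts, and an unadjusted odds-ratio
    Statistic computed from the counts.  All studies reference the same
    variable resources, so the whole set shares one variable signature.
    """
    rng = np.random.default_rng(cfg.seed)
    resources: list[m.AnyResource] = _shared_variables()
    for i in range(1, cfg.k + 1):
        counts = draw_counts(cfg, rng)
        estimate = compute_odds_ratio(counts)
        stat = to_statistic(
            estimate,
            sample=m.SampleSize(
                total_participants=counts.n_exposed + counts.n_reference,
                known_data_count=counts.n_exposed + counts.n_reference,
                number_of_studies=1,
            ),
            description=(
                f"unadjusted odds ratio from counts "
                f"{counts.events_exposed}/{counts.n_exposed} vs "
                f"{counts.events_reference}/{counts.n_reference}"
            ),
        )
        stat.number_of_events = counts.events_exposed + counts.events_reference
        resources.append(
            m.EvidenceResource(
                id=f"sim-evidence-{i}",
                title=f"Simulated study {i}",
                variable_definition=[
                    m.VariableDefinition(
                        variable_role="population",
                        observed=m.Reference(target="Group/sim-group-population"),
                    ),
                    m.VariableDefinition(
                        variable_role="exposure",
                        intended=m.Reference(
                            target="EvidenceVariable/sim-variable-exposure"
                        ),
                    ),
                    m.VariableDefinition(
                        variable_role="reference-exposure",
                        intended=m.Reference(
                            target="EvidenceVariable/sim-variable-reference"
                        ),
                    ),
                    m.VariableDefinition(
                        variable_role="measured-variable",
                        intended=m.Reference(
                            target="EvidenceVariable/sim-variable-outcome"
                        ),
                    ),
                ],
                statistic=[stat],
            )
        )
    return resources
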