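"""Domain types for computable evidence resources.

The types mirror the FHIR evidence-exchange resources (Evidence,
EvidenceVariable, Group, Citation, ArtifactAssessment) and the datatypes
they are built from (Coding, CodeableConcept, Quantity, ...), restricted to
the element subset this package supports.  Validation is issue-based:
:func:`validate_resource` walks a resource and returns a list of
:class:`ValidationIssue` rather than raising, so callers can report every
problem at once.

Two validation modes exist.  ``strict`` enforces terminology bindings
(statistic types against the packaged statistic-type value set, certainty
aspects against the nine-aspect list, variable roles against the six-role
list); ``lenient`` downgrades terminology-binding failures to warnings while
keeping structural invariants as errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Union

from .errors import UnknownResourceTypeError

__all__ = [
    "Coding",
    "CodeableConcept",
    "Quantity",
    "Range",
    "Reference",
    "Identifier",
    "VariableDefinition",
    "AttributeEstimate",
    "SampleSize",
    "ModelCharacteristic",
    "Statistic",
    "CertaintyRating",
    "EvidenceResource",
    "EvidenceVariableResource",
    "GroupCharacteristic",
    "GroupResource",
    "Contributor",
    "PublicationForm",
    "CitedArtifact",
    "CitationResource",
    "AssessmentContent",
    "ArtifactAssessmentResource",
    "ValidationIssue",
    "validate_resource",
    "resource_type_of",
    "VARIABLE_ROLES",
    "CERTAINTY_LEVELS",
    "INFORMATION_TYPES",
    "HANDLING_CODES",
]

#: The six variable roles a VariableDefinition may take.
VARIABLE_ROLES = (
    "population",
    "subpopulation",
    "exposure",
    "reference-exposure",
    "measured-variable",
    "confounder",
)

#: GRADE-style certainty levels.
CERTAINTY_LEVELS = ("high", "moderate", "low", "very-low")

INFORMATION_TYPES = ("comment", "classifier", "rating", "response", "change-request")

HANDLING_CODES = ("continuous", "dichotomous", "ordinal", "polychotomous")


# ---------------------------------------------------------------------------
# Datatypes
# ---------------------------------------------------------------------------


@dataclass
class Coding:
    """A terminology-bound code: system URI + code + human-readable display."""

    system: Optional[str] = None
    code: Optional[str] = None
    display: Optional[str] = None

    def key(self) -> tuple:
        return (self.system, self.code)


@dataclass
class CodeableConcept:
    """Zero or more Codings plus optional free text.

    A concept may be coded in several terminologies at once (e.g. the same
    disease in both SNOMED CT and ICD-10) and/or carried as plain text.
    """

    coding: list[Coding] = field(default_factory=list)
    text: Optional[str] = None

    def is_empty(self) -> bool:
        return not self.coding and not self.text

    def first_code(self, system: Optional[str] = None) -> Optional[str]:
        """Code of the first Coding, optionally restricted to one system."""
        for c in self.coding:
            if system is None or c.system == system:
                return c.code
        return None

    @classmethod
    def from_text(cls, text: str) -> "CodeableConcept":
        return cls(text=text)


@dataclass
class Quantity:
    """A decimal value with an optional unit and comparator."""

    value: float
    unit: Optional[str] = None
    comparator: Optional[str] = None  # one of < <= >= >


@dataclass
class Range:
    low: Optional[Quantity] = None
    high: Optional[Quantity] = None


@dataclass
class Reference:
    """A link to another resource: ``Type/id``, a bare id, or a URI."""

    target: str
    display: Optional[str] = None
    resolved_type: Optional[str] = None


@dataclass
class Identifier:
    """A typed identifier such as a DOI or PMID."""

    type: str
    value: str


# ---------------------------------------------------------------------------
# Evidence backbone
# ---------------------------------------------------------------------------


@dataclass
class VariableDefinition:
    """One variable an Evidence resource is about, with its role.

    ``observed`` and ``intended`` reference EvidenceVariable or Group
    resources; at least one must be present.
    """

    variable_role: str
    description: Optional[str] = None
    observed: Optional[Reference] = None
    intended: Optional[Reference] = None


@dataclass
class AttributeEstimate:
    """A statistic's companion quantity: CI/CrI, P value, heterogeneity..."""

    type: CodeableConcept
    quantity: Optional[Quantity] = None
    level: Optional[float] = None  # e.g. 0.95; strictly in (0, 1)
    range_low: Optional[Quantity] = None
    range_high: Optional[Quantity] = None
    nested: list["AttributeEstimate"] = field(default_factory=list)


@dataclass
class SampleSize:
    total_participants: Optional[int] = None
    known_data_count: Optional[int] = None
    number_of_studies: Optional[int] = None


@dataclass
class ModelCharacteristic:
    """A coded statistical-model attribute, optionally with a value."""

    code: CodeableConcept
    value: Optional[Quantity] = None
    variables: list[Reference] = field(default_factory=list)


@dataclass
class Statistic:
    """A machine-interpretable statistical finding."""

    statistic_type: CodeableConcept
    description: Optional[str] = None
    quantity: Optional[Quantity] = None
    number_of_events: Optional[int] = None
    sample_size: Optional[SampleSize] = None
    attribute_estimate: list[AttributeEstimate] = field(default_factory=list)
    model_characteristic: list[ModelCharacteristic] = field(default_factory=list)


@dataclass
class CertaintyRating:
    """A rating of one certainty aspect, optionally with sub-aspect ratings."""

    type: CodeableConcept
    rating: CodeableConcept
    rater: Optional[str] = None
    subcomponents: list["CertaintyRating"] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------


@dataclass
class EvidenceResource:
    """One unit of evidence: variables by role, statistics, certainty."""

    id: str
    title: Optional[str] = None
    description: Optional[str] = None
    variable_definition: list[VariableDefinition] = field(default_factory=list)
    statistic: list[Statistic] = field(default_factory=list)
    certainty: list[CertaintyRating] = field(default_factory=list)
    retained: dict[str, Any] = field(default_factory=dict, repr=False, compare=False)


@dataclass
class EvidenceVariableResource:
    """Definition of a single variable (exposure, outcome, ...)."""

    id: str
    name: Optional[str] = None
    definition: Optional[CodeableConcept] = None
    description: Optional[str] = None
    handling: Optional[str] = None
    retained: dict[str, Any] = field(default_factory=dict, repr=False, compare=False)


@dataclass
class GroupCharacteristic:
    code: CodeableConcept
    value: Union[CodeableConcept, Quantity, Range, None] = None
    exclude: bool = False


@dataclass
class GroupResource:
    """A group of people (population, sample, arm) defined by characteristics."""

    id: str
    name: Optional[str] = None
    characteristics: list[GroupCharacteristic] = field(default_factory=list)
    member_count: Optional[int] = None
    retained: dict[str, Any] = field(default_factory=dict, repr=False, compare=False)


@dataclass
class Contributor:
    name: str
    roles: list[str] = field(default_factory=list)
    affiliations: list[str] = field(default_factory=list)


@dataclass
class PublicationForm:
    published_in_title: Optional[str] = None
    date: Optional[str] = None
    volume: Optional[str] = None
    issue: Optional[str] = None
    first_page: Optional[str] = None
    last_page: Optional[str] = None


@dataclass
class CitedArtifact:
    identifiers: list[Identifier] = field(default_factory=list)
    title: Optional[str] = None
    abstract: Optional[str] = None
    publication_form: Optional[PublicationForm] = None
    web_locations: list[str] = field(default_factory=list)
    contributorship: list[Contributor] = field(default_factory=list)
    classifiers: list[CodeableConcept] = field(default_factory=list)


@dataclass
class CitationResource:
    """Identification/attribution metadata for a knowledge artifact."""

    id: str
    summary: Optional[str] = None
    cited_artifact: CitedArtifact = field(default_factory=CitedArtifact)
    retained: dict[str, Any] = field(default_factory=dict, repr=False, compare=False)


@dataclass
class AssessmentContent:
    """One comment/classifier/rating about an artifact."""

    information_type: str
    type: Optional[CodeableConcept] = None
    classifiers: list[CodeableConcept] = field(default_factory=list)
    rating_quantity: Optional[Quantity] = None
    author: Optional[str] = None
    path: Optional[str] = None
    components: list["AssessmentContent"] = field(default_factory=list)


@dataclass
class ArtifactAssessmentResource:
    """Comments, classifiers, and ratings about another resource."""

    id: str
    artifact: Union[Reference, str, None] = None
    content: list[AssessmentContent] = field(default_factory=list)
    retained: dict[str, Any] = field(default_factory=dict, repr=False, compare=False)


RESOURCE_TYPES = {
    EvidenceResource: "Evidence",
    EvidenceVariableResource: "EvidenceVariable",
    GroupResource: "Group",
    CitationResource: "Citation",
    ArtifactAssessmentResource: "ArtifactAssessment",
}

AnyResource = Union[
    EvidenceResource,
    EvidenceVariableResource,
    GroupResource,
    CitationResource,
    ArtifactAssessmentResource,
]


def resource_type_of(resource: Any) -> str:
    """Return the resource-type token for a modeled resource.

    Raises
    ------
    UnknownResourceTypeError
        If ``resource`` is not one of the five supported resource types.
    """
    token = RESOURCE_TYPES.get(type(resource))
    if token is None:
        raise UnknownResourceTypeError(
            f"not a supported resource: {type(resource).__name__!r}"
        )
    return token


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str  # dotted element path with bracketed indices
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.severity}: {self.path}: {self.message}"


class _Collector:
    def __init__(self, mode: str):
        self.mode = mode
        self.issues: list[ValidationIssue] = []

    def error(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue("error", path, message))

    def warning(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue("warning", path, message))

    def binding(self, path: str, message: str) -> None:
        """Terminology-binding failure: error in strict, warning in lenient."""
        if self.mode == "strict":
            self.error(path, message)
        else:
            self.warning(path, message)


def _check_coding(c: Coding, path: str, col: _Collector) -> None:
    if c.code is not None:
        if c.code != c.code.strip():
            col.error(f"{path}.code", "code has leading/trailing whitespace")
        if not c.system:
            col.binding(f"{path}.system", "code present without a system")


def _check_concept(
    cc: Optional[CodeableConcept], path: str, col: _Collector, required: bool = False
) -> None:
    if cc is None:
        if required:
            col.error(path, "required concept is absent")
        return
    if required and cc.is_empty():
        col.error(path, "concept has neither coding nor text")
    seen: set[tuple] = set()
    for i, c in enumerate(cc.coding):
        _check_coding(c, f"{path}.coding[{i}]", col)
        k = c.key()
        if k in seen:
            col.error(f"{path}.coding[{i}]", f"duplicate (system, code) pair {k}")
        seen.add(k)


def _check_quantity(q: Optional[Quantity], path: str, col: _Collector) -> None:
    if q is None:
        return
    if q.value is None or not math.isfinite(q.value):
        col.error(f"{path}.value", "quantity value must be finite")
    if q.comparator is not None and q.comparator not in ("<", "<=", ">=", ">"):
        col.error(f"{path}.comparator", f"invalid comparator {q.comparator!r}")


def _check_count(value: Optional[int], path: str, col: _Collector) -> None:
    if value is not None and value < 0:
        col.error(path, "count must be >= 0")


def _check_attribute_estimate(
    ae: AttributeEstimate, path: str, col: _Collector
) -> None:
    _check_concept(ae.type, f"{path}.type", col, required=True)
    _check_quantity(ae.quantity, f"{path}.quantity", col)
    _check_quantity(ae.range_low, f"{path}.range.low", col)
    _check_quantity(ae.range_high, f"{path}.range.high", col)
    if ae.level is not None and not (0.0 < ae.level < 1.0):
        col.error(f"{path}.level", f"level must lie strictly in (0, 1), got {ae.level}")
    if (
        ae.range_low is not None
        and ae.range_high is not None
        and ae.range_low.value > ae.range_high.value
    ):
        col.error(f"{path}.range", "range low exceeds range high")
    for i, sub in enumerate(ae.nested):
        _check_attribute_estimate(sub, f"{path}.attributeEstimate[{i}]", col)


def _check_statistic(s: Statistic, path: str, col: _Collector, registry) -> None:
    _check_concept(s.statistic_type, f"{path}.statisticType", col, required=True)
    if registry is not None and s.statistic_type is not None:
        from .terminology import validate_code  # local import: avoid cycle

        vs = registry.value_sets.get("statistic-type")
        if vs is not None:
            status = validate_code(s.statistic_type, vs, registry)
            if status == "invalid":
                col.binding(
                    f"{path}.statisticType",
                    "not in the statistic-type value set",
                )
    _check_quantity(s.quantity, f"{path}.quantity", col)
    _check_count(s.number_of_events, f"{path}.numberOfEvents", col)
    if s.sample_size is not None:
        sz = s.sample_size
        sp = f"{path}.sampleSize"
        _check_count(sz.total_participants, f"{sp}.numberOfParticipants", col)
        _check_count(sz.known_data_count, f"{sp}.knownDataCount", col)
        _check_count(sz.number_of_studies, f"{sp}.numberOfStudies", col)
        if (
            sz.total_participants is not None
            and sz.known_data_count is not None
            and sz.known_data_count > sz.total_participants
        ):
            col.error(
                f"{sp}.knownDataCount",
                "knownDataCount exceeds numberOfParticipants",
            )
        if (
            s.number_of_events is not None
            and sz.known_data_count is not None
            and s.number_of_events > sz.known_data_count
        ):
            col.error(
                f"{path}.numberOfEvents",
                "numberOfEvents exceeds sampleSize.knownDataCount",
            )
    for i, ae in enumerate(s.attribute_estimate):
        _check_attribute_estimate(ae, f"{path}.attributeEstimate[{i}]", col)
    for i, mc in enumerate(s.model_characteristic):
        mp = f"{path}.modelCharacteristic[{i}]"
        _check_concept(mc.code, f"{mp}.code", col, required=True)
        _check_quantity(mc.value, f"{mp}.value", col)


def _check_certainty(
    cr: CertaintyRating, path: str, col: _Collector, registry, depth: int
) -> None:
    if depth > 2:
        col.error(path, "certainty nesting exceeds depth 2 (overall -> aspect)")
        return
    _check_concept(cr.type, f"{path}.type", col, required=True)
    _check_concept(cr.rating, f"{path}.rating", col, required=True)
    if registry is not None:
        from .terminology import validate_code

        vs = registry.value_sets.get("certainty-aspect")
        if vs is not None and cr.type is not None:
            if validate_code(cr.type, vs, registry) == "invalid":
                col.binding(f"{path}.type", "not a recognized certainty aspect")
        rvs = registry.value_sets.get("certainty-rating")
        if rvs is not None and cr.rating is not None:
            if validate_code(cr.rating, rvs, registry) == "invalid":
                col.binding(
                    f"{path}.rating",
                    "not a certainty level or modifier code",
                )
    for i, sub in enumerate(cr.subcomponents):
        _check_certainty(sub, f"{path}.subcomponent[{i}]", col, registry, depth + 1)


def _check_reference(
    ref: Optional[Reference], path: str, col: _Collector, required: bool = False
) -> None:
    if ref is None:
        if required:
            col.error(path, "required reference is absent")
        return
    if not ref.target:
        col.error(f"{path}.target", "reference target is empty")


def _validate_evidence(r: EvidenceResource, col: _Collector, registry) -> None:
    root = "Evidence"
    if not r.variable_definition:
        col.error(
            f"{root}.variableDefinition",
            "at least one variableDefinition is required (cardinality 1..*)",
        )
    n_population = 0
    for i, vd in enumerate(r.variable_definition):
        p = f"{root}.variableDefinition[{i}]"
        if vd.variable_role == "population":
            n_population += 1
        if vd.variable_role not in VARIABLE_ROLES:
            col.binding(
                f"{p}.variableRole",
                f"role {vd.variable_role!r} not in the variable-role code list",
            )
        if vd.observed is None and vd.intended is None:
            col.error(p, "at least one of observed or intended is required")
        _check_reference(vd.observed, f"{p}.observed", col)
        _check_reference(vd.intended, f"{p}.intended", col)
    if n_population > 1:
        col.error(
            f"{root}.variableDefinition",
            f"at most one variableDefinition may have role population "
            f"(found {n_population})",
        )
    for i, s in enumerate(r.statistic):
        _check_statistic(s, f"{root}.statistic[{i}]", col, registry)
    for i, c in enumerate(r.certainty):
        _check_certainty(c, f"{root}.certainty[{i}]", col, registry, depth=1)


def _validate_evidence_variable(
    r: EvidenceVariableResource, col: _Collector, registry
) -> None:
    root = "EvidenceVariable"
    has_def = r.definition is not None and not r.definition.is_empty()
    if not r.name and not has_def and not r.description:
        col.error(root, "a name or definition is required")
    _check_concept(r.definition, f"{root}.definition", col)
    if r.handling is not None and r.handling not in HANDLING_CODES:
        col.binding(f"{root}.handling", f"unknown handling code {r.handling!r}")


def _validate_group(r: GroupResource, col: _Collector, registry) -> None:
    root = "Group"
    _check_count(r.member_count, f"{root}.quantity", col)
    for i, ch in enumerate(r.characteristics):
        p = f"{root}.characteristic[{i}]"
        _check_concept(ch.code, f"{p}.code", col, required=True)
        if isinstance(ch.value, CodeableConcept):
            _check_concept(ch.value, f"{p}.valueCodeableConcept", col)
        elif isinstance(ch.value, Quantity):
            _check_quantity(ch.value, f"{p}.valueQuantity", col)
        elif isinstance(ch.value, Range):
            _check_quantity(ch.value.low, f"{p}.valueRange.low", col)
            _check_quantity(ch.value.high, f"{p}.valueRange.high", col)


def _validate_citation(r: CitationResource, col: _Collector, registry) -> None:
    root = "Citation"
    ca = r.cited_artifact
    if not ca.title and not ca.identifiers:
        col.error(
            f"{root}.citedArtifact",
            "a title or at least one identifier is required",
        )
    for i, ident in enumerate(ca.identifiers):
        if not ident.value:
            col.error(f"{root}.citedArtifact.identifier[{i}].value", "empty value")
    for i, cc in enumerate(ca.classifiers):
        _check_concept(cc, f"{root}.citedArtifact.classifier[{i}]", col)


def _check_assessment_content(
    c: AssessmentContent, path: str, col: _Collector
) -> None:
    if not c.information_type:
        col.error(f"{path}.informationType", "informationType is required")
    elif c.information_type not in INFORMATION_TYPES:
        col.error(
            f"{path}.informationType",
            f"unknown information type {c.information_type!r}",
        )
    if c.rating_quantity is not None and c.information_type != "rating":
        col.error(
            f"{path}.quantity",
            "rating quantity only allowed when informationType is 'rating'",
        )
    _check_quantity(c.rating_quantity, f"{path}.quantity", col)
    if c.type is not None:
        _check_concept(c.type, f"{path}.type", col)
    for i, cc in enumerate(c.classifiers):
        _check_concept(cc, f"{path}.classifier[{i}]", col)
    for i, sub in enumerate(c.components):
        _check_assessment_content(sub, f"{path}.component[{i}]", col)


def _validate_artifact_assessment(
    r: ArtifactAssessmentResource, col: _Collector, registry
) -> None:
    root = "ArtifactAssessment"
    if isinstance(r.artifact, Reference):
        _check_reference(r.artifact, f"{root}.artifactReference", col)
    for i, c in enumerate(r.content):
        _check_assessment_content(c, f"{root}.content[{i}]", col)


_VALIDATORS = {
    EvidenceResource: _validate_evidence,
    EvidenceVariableResource: _validate_evidence_variable,
    GroupResource: _validate_group,
    CitationResource: _validate_citation,
    ArtifactAssessmentResource: _validate_artifact_assessment,
}

_default_registry = None


def _get_default_registry():
    global _default_registry
    if _default_registry is None:
        from .terminology import load_packaged_terminologies

        _default_registry = load_packaged_terminologies()
    return _default_registry


def validate_resource(
    resource: Any, mode: str = "strict", registry=None
) -> list[ValidationIssue]:
    """Validate a resource, returning all issues found.

    Parameters
    ----------
    resource
        Any of the five supported resource types.
    mode
        ``"strict"`` treats terminology-binding failures as errors;
        ``"lenient"`` downgrades them to warnings.  Structural invariants
        (cardinalities, count ordering, range ordering) are errors in both.
    registry
        Terminology registry used for code bindings; defaults to the
        packaged one.

    Returns
    -------
    list of ValidationIssue
        Empty iff every invariant and cardinality holds.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    token = resource_type_of(resource)  # raises for unknown types
    if registry is None:
        registry = _get_default_registry()
    col = _Collector(mode)
    if not getattr(resource, "id", None):
        col.error(f"{token}.id", "resource id is required")
    _VALIDATORS[type(resource)](resource, col, registry)
    return col.issues
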