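"""FHIR-JSON serialization: parse, write, bundle handling.

Single resources are one JSON document each; bundles are newline-delimited
JSON (``.ndjson``), one resource per line.  Writing is canonical and
deterministic: ``resourceType`` first, fixed key order, no insignificant
whitespace (unless pretty-printed), so identical resources produce
byte-identical output.

Unknown elements: ``strict`` parsing rejects them; ``lenient`` parsing
retains the raw fragments keyed by element path and re-injects them
verbatim on write, so a lenient round-trip is lossless even for elements
this package does not model.  Choice-typed values follow the FHIR
``value[x]`` naming convention (``valueCodeableConcept``, ``valueQuantity``,
``valueRange``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Optional, Union

from . import model as m
from .errors import (
    BundleError,
    MalformedDocumentError,
    SerializationError,
    UnknownResourceTypeError,
    UnsupportedElementError,
)

__all__ = [
    "ParseReport",
    "parse_resource",
    "write_resource",
    "read_bundle",
    "write_bundle",
    "Resolver",
]


@dataclass
class ParseReport:
    """Result of parsing one document: the resource plus what was set aside."""

    resource: m.AnyResource
    retained: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


class _Ctx:
    def __init__(self, mode: str):
        self.mode = mode
        self.retained: dict[str, Any] = {}
        self.warnings: list[str] = []

    def unknown(self, d: dict, path: str) -> None:
        """Handle keys left over after all known ones were consumed."""
        for key, value in d.items():
            kpath = f"{path}.{key}" if path else key
            if self.mode == "strict":
                raise UnsupportedElementError(f"unknown element {kpath!r}")
            self.retained[kpath] = value
            self.warnings.append(f"retained unknown element {kpath!r}")


# ---------------------------------------------------------------------------
# Datatype parse/serialize pairs
# ---------------------------------------------------------------------------


def _prune(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None and v != [] and v != {}}


def _ser_coding(c: m.Coding) -> dict:
    return _prune({"system": c.system, "code": c.code, "display": c.display})


def _parse_coding(d: dict, path: str, ctx: _Ctx) -> m.Coding:
    d = dict(d)
    out = m.Coding(
        system=d.pop("system", None),
        code=d.pop("code", None),
        display=d.pop("display", None),
    )
    ctx.unknown(d, path)
    return out


def _ser_concept(cc: m.CodeableConcept) -> dict:
    return _prune(
        {"coding": [_ser_coding(c) for c in cc.coding], "text": cc.text}
    )


def _parse_concept(d: dict, path: str, ctx: _Ctx) -> m.CodeableConcept:
    d = dict(d)
    coding = [
        _parse_coding(c, f"{path}.coding[{i}]", ctx)
        for i, c in enumerate(d.pop("coding", []))
    ]
    out = m.CodeableConcept(coding=coding, text=d.pop("text", None))
    ctx.unknown(d, path)
    return out


def _ser_quantity(q: m.Quantity) -> dict:
    return _prune({"value": q.value, "comparator": q.comparator, "unit": q.unit})


def _parse_quantity(d: dict, path: str, ctx: _Ctx) -> m.Quantity:
    d = dict(d)
    out = m.Quantity(
        value=d.pop("value", None),
        comparator=d.pop("comparator", None),
        unit=d.pop("unit", None),
    )
    ctx.unknown(d, path)
    return out


def _ser_reference(r: m.Reference) -> dict:
    return _prune(
        {"reference": r.target, "type": r.resolved_type, "display": r.display}
    )


def _parse_reference(d: dict, path: str, ctx: _Ctx) -> m.Reference:
    d = dict(d)
    out = m.Reference(
        target=d.pop("reference", ""),
        resolved_type=d.pop("type", None),
        display=d.pop("display", None),
    )
    ctx.unknown(d, path)
    return out


# ---------------------------------------------------------------------------
# Evidence backbone
# ---------------------------------------------------------------------------


def _ser_attribute_estimate(ae: m.AttributeEstimate) -> dict:
    rng = _prune(
        {
            "low": _ser_quantity(ae.range_low) if ae.range_low else None,
            "high": _ser_quantity(ae.range_high) if ae.range_high else None,
        }
    )
    return _prune(
        {
            "type": _ser_concept(ae.type),
            "quantity": _ser_quantity(ae.quantity) if ae.quantity else None,
            "level": ae.level,
            "range": rng or None,
            "attributeEstimate": [_ser_attribute_estimate(x) for x in ae.nested],
        }
    )


def _parse_attribute_estimate(d: dict, path: str, ctx: _Ctx) -> m.AttributeEstimate:
    d = dict(d)
    rng = d.pop("range", None) or {}
    rng = dict(rng)
    low = rng.pop("low", None)
    high = rng.pop("high", None)
    ctx.unknown(rng, f"{path}.range")
    quantity = d.pop("quantity", None)
    out = m.AttributeEstimate(
        type=_parse_concept(d.pop("type", {}), f"{path}.type", ctx),
        quantity=_parse_quantity(quantity, f"{path}.quantity", ctx)
        if quantity
        else None,
        level=d.pop("level", None),
        range_low=_parse_quantity(low, f"{path}.range.low", ctx) if low else None,
        range_high=_parse_quantity(high, f"{path}.range.high", ctx) if high else None,
        nested=[
            _parse_attribute_estimate(x, f"{path}.attributeEstimate[{i}]", ctx)
            for i, x in enumerate(d.pop("attributeEstimate", []))
        ],
    )
    ctx.unknown(d, path)
    return out


def _ser_sample_size(s: m.SampleSize) -> dict:
    return _prune(
        {
            "numberOfStudies": s.number_of_studies,
            "numberOfParticipants": s.total_participants,
            "knownDataCount": s.known_data_count,
        }
    )


def _parse_sample_size(d: dict, path: str, ctx: _Ctx) -> m.SampleSize:
    d = dict(d)
    out = m.SampleSize(
        number_of_studies=d.pop("numberOfStudies", None),
        total_participants=d.pop("numberOfParticipants", None),
        known_data_count=d.pop("knownDataCount", None),
    )
    ctx.unknown(d, path)
    return out


def _ser_model_characteristic(mc: m.ModelCharacteristic) -> dict:
    return _prune(
        {
            "code": _ser_concept(mc.code),
            "value": _ser_quantity(mc.value) if mc.value else None,
            "variable": [_ser_reference(v) for v in mc.variables],
        }
    )


def _parse_model_characteristic(
    d: dict, path: str, ctx: _Ctx
) -> m.ModelCharacteristic:
    d = dict(d)
    value = d.pop("value", None)
    out = m.ModelCharacteristic(
        code=_parse_concept(d.pop("code", {}), f"{path}.code", ctx),
        value=_parse_quantity(value, f"{path}.value", ctx) if value else None,
        variables=[
            _parse_reference(v, f"{path}.variable[{i}]", ctx)
            for i, v in enumerate(d.pop("variable", []))
        ],
    )
    ctx.unknown(d, path)
    return out


def _ser_statistic(s: m.Statistic) -> dict:
    return _prune(
        {
            "description": s.description,
            "statisticType": _ser_concept(s.statistic_type),
            "quantity": _ser_quantity(s.quantity) if s.quantity else None,
            "numberOfEvents": s.number_of_events,
            "sampleSize": _ser_sample_size(s.sample_size) if s.sample_size else None,
            "attributeEstimate": [
                _ser_attribute_estimate(a) for a in s.attribute_estimate
            ],
            "modelCharacteristic": [
                _ser_model_characteristic(c) for c in s.model_characteristic
            ],
        }
    )


def _parse_statistic(d: dict, path: str, ctx: _Ctx) -> m.Statistic:
    d = dict(d)
    quantity = d.pop("quantity", None)
    sample = d.pop("sampleSize", None)
    out = m.Statistic(
        description=d.pop("description", None),
        statistic_type=_parse_concept(
            d.pop("statisticType", {}), f"{path}.statisticType", ctx
        ),
        quantity=_parse_quantity(quantity, f"{path}.quantity", ctx)
        if quantity
        else None,
        number_of_events=d.pop("numberOfEvents", None),
        sample_size=_parse_sample_size(sample, f"{path}.sampleSize", ctx)
        if sample
        else None,
        attribute_estimate=[
            _parse_attribute_estimate(a, f"{path}.attributeEstimate[{i}]", ctx)
            for i, a in enumerate(d.pop("attributeEstimate", []))
        ],
        model_characteristic=[
            _parse_model_characteristic(c, f"{path}.modelCharacteristic[{i}]", ctx)
            for i, c in enumerate(d.pop("modelCharacteristic", []))
        ],
    )
    ctx.unknown(d, path)
    return out


def _ser_certainty(c: m.CertaintyRating) -> dict:
    return _prune(
        {
            "type": _ser_concept(c.type),
            "rating": _ser_concept(c.rating),
            "rater": c.rater,
            "subcomponent": [_ser_certainty(s) for s in c.subcomponents],
        }
    )


def _parse_certainty(d: dict, path: str, ctx: _Ctx) -> m.CertaintyRating:
    d = dict(d)
    out = m.CertaintyRating(
        type=_parse_concept(d.pop("type", {}), f"{path}.type", ctx),
        rating=_parse_concept(d.pop("rating", {}), f"{path}.rating", ctx),
        rater=d.pop("rater", None),
        subcomponents=[
            _parse_certainty(s, f"{path}.subcomponent[{i}]", ctx)
            for i, s in enumerate(d.pop("subcomponent", []))
        ],
    )
    ctx.unknown(d, path)
    return out


def _ser_variable_definition(vd: m.VariableDefinition) -> dict:
    return _prune(
        {
            "description": vd.description,
            "variableRole": vd.variable_role,
            "observed": _ser_reference(vd.observed) if vd.observed else None,
            "intended": _ser_reference(vd.intended) if vd.intended else None,
        }
    )


def _parse_variable_definition(
    d: dict, path: str, ctx: _Ctx
) -> m.VariableDefinition:
    d = dict(d)
    observed = d.pop("observed", None)
    intended = d.pop("intended", None)
    role = d.pop("variableRole", None)
    if isinstance(role, dict):  # accept CodeableConcept-shaped roles
        cc = _parse_concept(role, f"{path}.variableRole", ctx)
        role = cc.first_code() or cc.text
    out = m.VariableDefinition(
        variable_role=role,
        description=d.pop("description", None),
        observed=_parse_reference(observed, f"{path}.observed", ctx)
        if observed
        else None,
        intended=_parse_reference(intended, f"{path}.intended", ctx)
        if intended
        else None,
    )
    ctx.unknown(d, path)
    return out


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------


def _ser_evidence(r: m.EvidenceResource) -> dict:
    return _prune(
        {
            "resourceType": "Evidence",
            "id": r.id,
            "title": r.title,
            "description": r.description,
            "variableDefinition": [
                _ser_variable_definition(v) for v in r.variable_definition
            ],
            "statistic": [_ser_statistic(s) for s in r.statistic],
            "certainty": [_ser_certainty(c) for c in r.certainty],
        }
    )


def _parse_evidence(d: dict, ctx: _Ctx) -> m.EvidenceResource:
    d = dict(d)
    out = m.EvidenceResource(
        id=d.pop("id", None),
        title=d.pop("title", None),
        description=d.pop("description", None),
        variable_definition=[
            _parse_variable_definition(v, f"variableDefinition[{i}]", ctx)
            for i, v in enumerate(d.pop("variableDefinition", []))
        ],
        statistic=[
            _parse_statistic(s, f"statistic[{i}]", ctx)
            for i, s in enumerate(d.pop("statistic", []))
        ],
        certainty=[
            _parse_certainty(c, f"certainty[{i}]", ctx)
            for i, c in enumerate(d.pop("certainty", []))
        ],
    )
    ctx.unknown(d, "")
    return out


def _ser_evidence_variable(r: m.EvidenceVariableResource) -> dict:
    return _prune(
        {
            "resourceType": "EvidenceVariable",
            "id": r.id,
            "name": r.name,
            "description": r.description,
            "definition": _ser_concept(r.definition) if r.definition else None,
            "handling": r.handling,
        }
    )


def _parse_evidence_variable(d: dict, ctx: _Ctx) -> m.EvidenceVariableResource:
    d = dict(d)
    definition = d.pop("definition", None)
    out = m.EvidenceVariableResource(
        id=d.pop("id", None),
        name=d.pop("name", None),
        description=d.pop("description", None),
        definition=_parse_concept(definition, "definition", ctx)
        if definition
        else None,
        handling=d.pop("handling", None),
    )
    ctx.unknown(d, "")
    return out


def _ser_group_characteristic(ch: m.GroupCharacteristic) -> dict:
    out: dict[str, Any] = {"code": _ser_concept(ch.code)}
    if isinstance(ch.value, m.CodeableConcept):
        out["valueCodeableConcept"] = _ser_concept(ch.value)
    elif isinstance(ch.value, m.Quantity):
        out["valueQuantity"] = _ser_quantity(ch.value)
    elif isinstance(ch.value, m.Range):
        out["valueRange"] = _prune(
            {
                "low": _ser_quantity(ch.value.low) if ch.value.low else None,
                "high": _ser_quantity(ch.value.high) if ch.value.high else None,
            }
        )
    if ch.exclude:
        out["exclude"] = True
    return out


def _parse_group_characteristic(
    d: dict, path: str, ctx: _Ctx
) -> m.GroupCharacteristic:
    d = dict(d)
    value: Union[m.CodeableConcept, m.Quantity, m.Range, None] = None
    if "valueCodeableConcept" in d:
        value = _parse_concept(
            d.pop("valueCodeableConcept"), f"{path}.valueCodeableConcept", ctx
        )
    elif "valueQuantity" in d:
        value = _parse_quantity(
            d.pop("valueQuantity"), f"{path}.valueQuantity", ctx
        )
    elif "valueRange" in d:
        rng = dict(d.pop("valueRange"))
        low = rng.pop("low", None)
        high = rng.pop("high", None)
        ctx.unknown(rng, f"{path}.valueRange")
        value = m.Range(
            low=_parse_quantity(low, f"{path}.valueRange.low", ctx) if low else None,
            high=_parse_quantity(high, f"{path}.valueRange.high", ctx)
            if high
            else None,
        )
    out = m.GroupCharacteristic(
        code=_parse_concept(d.pop("code", {}), f"{path}.code", ctx),
        value=value,
        exclude=bool(d.pop("exclude", False)),
    )
    ctx.unknown(d, path)
    return out


def _ser_group(r: m.GroupResource) -> dict:
    return _prune(
        {
            "resourceType": "Group",
            "id": r.id,
            "name": r.name,
            "quantity": r.member_count,
            "characteristic": [
                _ser_group_characteristic(c) for c in r.characteristics
            ],
        }
    )


def _parse_group(d: dict, ctx: _Ctx) -> m.GroupResource:
    d = dict(d)
    out = m.GroupResource(
        id=d.pop("id", None),
        name=d.pop("name", None),
        member_count=d.pop("quantity", None),
        characteristics=[
            _parse_group_characteristic(c, f"characteristic[{i}]", ctx)
            for i, c in enumerate(d.pop("characteristic", []))
        ],
    )
    ctx.unknown(d, "")
    return out


def _ser_citation(r: m.CitationResource) -> dict:
    ca = r.cited_artifact
    pf = ca.publication_form
    pf_doc = None
    if pf is not None:
        pf_doc = _prune(
            {
                "publishedIn": _prune({"title": pf.published_in_title}) or None,
                "date": pf.date,
                "volume": pf.volume,
                "issue": pf.issue,
                "firstPage": pf.first_page,
                "lastPage": pf.last_page,
            }
        )
    ca_doc = _prune(
        {
            "identifier": [
                {"type": i.type, "value": i.value} for i in ca.identifiers
            ],
            "title": ca.title,
            "abstract": ca.abstract,
            "publicationForm": pf_doc or None,
            "webLocation": [{"url": u} for u in ca.web_locations],
            "contributorship": [
                _prune(
                    {
                        "name": c.name,
                        "role": list(c.roles) or None,
                        "affiliation": list(c.affiliations) or None,
                    }
                )
                for c in ca.contributorship
            ],
            "classifier": [_ser_concept(c) for c in ca.classifiers],
        }
    )
    return _prune(
        {
            "resourceType": "Citation",
            "id": r.id,
            "summary": r.summary,
            "citedArtifact": ca_doc or None,
        }
    )


def _parse_citation(d: dict, ctx: _Ctx) -> m.CitationResource:
    d = dict(d)
    ca_doc = dict(d.pop("citedArtifact", {}) or {})
    pf_doc = ca_doc.pop("publicationForm", None)
    pf = None
    if pf_doc is not None:
        pf_doc = dict(pf_doc)
        published_in = dict(pf_doc.pop("publishedIn", {}) or {})
        pi_title = published_in.pop("title", None)
        ctx.unknown(published_in, "citedArtifact.publicationForm.publishedIn")
        pf = m.PublicationForm(
            published_in_title=pi_title,
            date=pf_doc.pop("date", None),
            volume=pf_doc.pop("volume", None),
            issue=pf_doc.pop("issue", None),
            first_page=pf_doc.pop("firstPage", None),
            last_page=pf_doc.pop("lastPage", None),
        )
        ctx.unknown(pf_doc, "citedArtifact.publicationForm")
    identifiers = []
    for i, ident in enumerate(ca_doc.pop("identifier", [])):
        ident = dict(ident)
        identifiers.append(
            m.Identifier(
                type=ident.pop("type", ""), value=ident.pop("value", "")
            )
        )
        ctx.unknown(ident, f"citedArtifact.identifier[{i}]")
    web_locations = []
    for i, loc in enumerate(ca_doc.pop("webLocation", [])):
        loc = dict(loc)
        web_locations.append(loc.pop("url", ""))
        ctx.unknown(loc, f"citedArtifact.webLocation[{i}]")
    contributors = []
    for i, con in enumerate(ca_doc.pop("contributorship", [])):
        con = dict(con)
        contributors.append(
            m.Contributor(
                name=con.pop("name", ""),
                roles=list(con.pop("role", [])),
                affiliations=list(con.pop("affiliation", [])),
            )
        )
        ctx.unknown(con, f"citedArtifact.contributorship[{i}]")
    classifiers = [
        _parse_concept(c, f"citedArtifact.classifier[{i}]", ctx)
        for i, c in enumerate(ca_doc.pop("classifier", []))
    ]
    ca = m.CitedArtifact(
        identifiers=identifiers,
        title=ca_doc.pop("title", None),
        abstract=ca_doc.pop("abstract", None),
        publication_form=pf,
        web_locations=web_locations,
        contributorship=contributors,
        classifiers=classifiers,
    )
    ctx.unknown(ca_doc, "citedArtifact")
    out = m.CitationResource(
        id=d.pop("id", None),
        summary=d.pop("summary", None),
        cited_artifact=ca,
    )
    ctx.unknown(d, "")
    return out


def _ser_assessment_content(c: m.AssessmentContent) -> dict:
    return _prune(
        {
            "informationType": c.information_type,
            "type": _ser_concept(c.type) if c.type else None,
            "classifier": [_ser_concept(x) for x in c.classifiers],
            "quantity": _ser_quantity(c.rating_quantity)
            if c.rating_quantity
            else None,
            "author": c.author,
            "path": c.path,
            "component": [_ser_assessment_content(x) for x in c.components],
        }
    )


def _parse_assessment_content(d: dict, path: str, ctx: _Ctx) -> m.AssessmentContent:
    d = dict(d)
    type_doc = d.pop("type", None)
    quantity = d.pop("quantity", None)
    out = m.AssessmentContent(
        information_type=d.pop("informationType", None),
        type=_parse_concept(type_doc, f"{path}.type", ctx) if type_doc else None,
        classifiers=[
            _parse_concept(x, f"{path}.classifier[{i}]", ctx)
            for i, x in enumerate(d.pop("classifier", []))
        ],
        rating_quantity=_parse_quantity(quantity, f"{path}.quantity", ctx)
        if quantity
        else None,
        author=d.pop("author", None),
        path=d.pop("path", None),
        components=[
            _parse_assessment_content(x, f"{path}.component[{i}]", ctx)
            for i, x in enumerate(d.pop("component", []))
        ],
    )
    ctx.unknown(d, path)
    return out


def _ser_artifact_assessment(r: m.ArtifactAssessmentResource) -> dict:
    out: dict[str, Any] = {"resourceType": "ArtifactAssessment", "id": r.id}
    if isinstance(r.artifact, m.Reference):
        out["artifactReference"] = _ser_reference(r.artifact)
    elif isinstance(r.artifact, str):
        out["artifactDisplay"] = r.artifact
    if r.content:
        out["content"] = [_ser_assessment_content(c) for c in r.content]
    return _prune(out)


def _parse_artifact_assessment(d: dict, ctx: _Ctx) -> m.ArtifactAssessmentResource:
    d = dict(d)
    artifact: Union[m.Reference, str, None] = None
    if "artifactReference" in d:
        artifact = _parse_reference(
            d.pop("artifactReference"), "artifactReference", ctx
        )
    elif "artifactDisplay" in d:
        artifact = d.pop("artifactDisplay")
    out = m.ArtifactAssessmentResource(
        id=d.pop("id", None),
        artifact=artifact,
        content=[
            _parse_assessment_content(c, f"content[{i}]", ctx)
            for i, c in enumerate(d.pop("content", []))
        ],
    )
    ctx.unknown(d, "")
    return out


_PARSERS = {
    "Evidence": _parse_evidence,
    "EvidenceVariable": _parse_evidence_variable,
    "Group": _parse_group,
    "Citation": _parse_citation,
    "ArtifactAssessment": _parse_artifact_assessment,
}

_SERIALIZERS = {
    m.EvidenceResource: _ser_evidence,
    m.EvidenceVariableResource: _ser_evidence_variable,
    m.GroupResource: _ser_group,
    m.CitationResource: _ser_citation,
    m.ArtifactAssessmentResource: _ser_artifact_assessment,
}


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def parse_resource(
    document: Union[str, dict], mode: str = "lenient"
) -> ParseReport:
    """Parse one FHIR-JSON document into a typed resource.

    Raises :class:`MalformedDocumentError` for bad JSON,
    :class:`UnknownResourceTypeError` for a missing or unsupported
    ``resourceType``, and (strict mode) :class:`UnsupportedElementError`
    for unknown elements.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if isinstance(document, str):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise MalformedDocumentError(f"not valid JSON: {exc}") from exc
    else:
        doc = document
    if not isinstance(doc, dict):
        raise MalformedDocumentError("document is not a JSON object")
    doc = dict(doc)
    rtype = doc.pop("resourceType", None)
    if rtype is None:
        raise UnknownResourceTypeError("document has no resourceType")
    parser = _PARSERS.get(rtype)
    if parser is None:
        raise UnknownResourceTypeError(f"unsupported resourceType {rtype!r}")
    ctx = _Ctx(mode)
    resource = parser(doc, ctx)
    resource.retained = ctx.retained
    return ParseReport(resource=resource, retained=ctx.retained, warnings=ctx.warnings)


_SEGMENT = re.compile(r"([A-Za-z][A-Za-z0-9]*)(?:\[(\d+)\])?$")


def _inject(doc: dict, path: str, value: Any) -> None:
    """Re-insert a retained fragment at its dotted/bracketed path."""
    parts = path.split(".")
    node: Any = doc
    for part in parts[:-1]:
        match = _SEGMENT.match(part)
        if match is None:
            raise SerializationError(f"malformed retained path {path!r}")
        name, index = match.group(1), match.group(2)
        if name not in node or not isinstance(node[name], (dict, list)):
            node[name] = [] if index is not None else {}
        node = node[name]
        if index is not None:
            i = int(index)
            if not isinstance(node, list) or i >= len(node):
                raise SerializationError(
                    f"retained path {path!r} indexes a missing element"
                )
            node = node[i]
    last = _SEGMENT.match(parts[-1])
    if last is None or last.group(2) is not None:
        raise SerializationError(f"malformed retained path {path!r}")
    node[last.group(1)] = value


def write_resource(
    resource: m.AnyResource,
    pretty: bool = False,
    validate: bool = True,
    registry=None,
) -> str:
    """Serialize a resource to canonical FHIR-JSON text.

    The resource must be at least lenient-clean (no structural errors);
    otherwise a :class:`SerializationError` carrying the issues is raised.
    Retained unknown elements (from a lenient parse) are re-injected
    verbatim, deterministically ordered by path.
    """
    ser = _SERIALIZERS.get(type(resource))
    if ser is None:
        raise UnknownResourceTypeError(
            f"not a supported resource: {type(resource).__name__!r}"
        )
    if validate:
        issues = [
            i
            for i in m.validate_resource(resource, mode="lenient", registry=registry)
            if i.severity == "error"
        ]
        if issues:
            raise SerializationError(
                f"refusing to write invalid resource: {issues[0]}", issues
            )
    doc = ser(resource)
    for path in sorted(getattr(resource, "retained", {})):
        _inject(doc, path, resource.retained[path])
    if pretty:
        return json.dumps(doc, indent=2, ensure_ascii=False)
    return json.dumps(doc, separators=(",", ":"), ensure_ascii=False)


def read_bundle(text: str, mode: str = "lenient") -> list[ParseReport]:
    """Read a bundle: a JSON array, one JSON object, or newline-delimited JSON.

    Order is preserved.  Duplicate resource ids (within a resource type)
    raise :class:`BundleError`.
    """
    text = text.strip()
    if not text:
        return []
    docs: list[Any]
    try:
        whole = json.loads(text)
        docs = whole if isinstance(whole, list) else [whole]
    except json.JSONDecodeError:
        docs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            try:
                docs.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise MalformedDocumentError(
                    f"line {lineno}: not valid JSON: {exc}"
                ) from exc
    reports = [parse_resource(d, mode=mode) for d in docs]
    seen: set[tuple[str, str]] = set()
    for rep in reports:
        key = (m.resource_type_of(rep.resource), rep.resource.id)
        if key in seen:
            raise BundleError(f"duplicate id {key[1]!r} for {key[0]} in bundle")
        seen.add(key)
    return reports


def write_bundle(resources, pretty: bool = False, validate: bool = True) -> str:
    """Serialize resources (or ParseReports) as newline-delimited JSON."""
    lines = []
    for r in resources:
        if isinstance(r, ParseReport):
            r = r.resource
        lines.append(write_resource(r, pretty=False, validate=validate))
    return "\n".join(lines) + ("\n" if lines else "")


class Resolver:
    """Reference resolution over a bundle: ``Type/id`` or bare-id targets."""

    def __init__(self, resources):
        self._by_key: dict[str, m.AnyResource] = {}
        for r in resources:
            if isinstance(r, ParseReport):
                r = r.resource
            rtype = m.resource_type_of(r)
            self._by_key[f"{rtype}/{r.id}"] = r
            self._by_key.setdefault(r.id, r)

    def resolve(self, ref: m.Reference) -> m.AnyResource:
        resource = self._by_key.get(ref.target)
        if resource is None:
            raise BundleError(f"unresolvable reference {ref.target!r}")
        return resource

    def __contains__(self, target: str) -> bool:
        return target in self._by_key
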