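"""Structural validation of the resource model."""

import copy

import pytest

import ebmkit as e
from ebmkit import model as m
from ebmkit.errors import UnknownResourceTypeError
from tests.conftest import all_resource_examples


def test_all_fixture_resources_strict_valid(registry):
    for resource in all_resource_examples():
        issues = e.validate_resource(resource, mode="strict", registry=registry)
        assert issues == [], f"{resource.id}: {[str(i) for i in issues]}"


def test_validation_is_pure(walkthrough, registry):
    ev = walkthrough.evidence[0]
    first = e.validate_resource(ev, registry=registry)
    second = e.validate_resource(ev, registry=registry)
    assert first == second


def test_evidence_without_variable_definition_is_error(walkthrough):
    ev = copy.deepcopy(walkthrough.evidence[0])
    ev.variable_definition = []
    issues = e.validate_resource(ev)
    errors = [i for i in issues if i.severity == "error"]
    assert len(errors) == 1
    assert "variableDefinition" in errors[0].path


def test_two_population_roles_rejected(walkthrough):
    ev = copy.deepcopy(walkthrough.evidence[0])
    for vd in ev.variable_definition[:2]:
        vd.variable_role = "population"
    issues = e.validate_resource(ev)
    assert any(
        "population" in i.message and i.severity == "error" for i in issues
    )


def test_events_exceeding_known_data_count_is_error():
    stat = m.Statistic(
        statistic_type=m.CodeableConcept(
            coding=[
                m.Coding(
                    system="urn:ebmkit:codesystem:statistic-type",
                    code="count",
                    display="count",
                )
            ]
        ),
        number_of_events=50,
        sample_size=m.SampleSize(known_data_count=40),
    )
    ev = m.EvidenceResource(
        id="x",
        variable_definition=[
            m.VariableDefinition(
                variable_role="exposure", intended=m.Reference(target="E/1")
            )
        ],
        statistic=[stat],
    )
    issues = e.validate_resource(ev)
    errors = [i for i in issues if i.severity == "error"]
    assert len(errors) == 1
    assert "numberOfEvents" in errors[0].path


@pytest.mark.parametrize(
    "mutate, expected_path_fragment",
    [
        (lambda ev: setattr(ev, "id", None), "id"),
        (
            lambda ev: setattr(ev.variable_definition[0], "observed", None)
            or setattr(ev.variable_definition[0], "intended", None),
            "variableDefinition[0]",
        ),
        (
            lambda ev: setattr(
                ev.statistic[0], "statistic_type", m.CodeableConcept()
            ),
            "statisticType",
        ),
    ],
)
def test_removing_required_element_names_it(walkthrough, mutate,
                                            expected_path_fragment):
    ev = copy.deepcopy(walkthrough.evidence[0])
    mutate(ev)
    issues = [i for i in e.validate_resource(ev) if i.severity == "error"]
    assert issues
    assert any(expected_path_fragment in i.path for i in issues)


def test_lenient_downgrades_terminology_failures(walkthrough):
    ev = copy.deepcopy(walkthrough.evidence[0])
    ev.statistic[0].statistic_type = m.CodeableConcept(
        coding=[m.Coding(system="urn:other", code="mystery-statistic")]
    )
    strict = e.validate_resource(ev, mode="strict")
    lenient = e.validate_resource(ev, mode="lenient")
    assert any(i.severity == "error" for i in strict)
    assert all(i.severity == "warning" for i in lenient)


def test_bare_code_without_system_flagged_in_strict():
    group = m.GroupResource(
        id="g",
        name="g",
        characteristics=[
            m.GroupCharacteristic(
                code=m.CodeableConcept(coding=[m.Coding(code="naked")])
            )
        ],
    )
    strict = e.validate_resource(group, mode="strict")
    assert any("system" in i.path and i.severity == "error" for i in strict)
    lenient = e.validate_resource(group, mode="lenient")
    assert all(i.severity == "warning" for i in lenient)


def test_duplicate_codings_rejected():
    cc = m.CodeableConcept(
        coding=[
            m.Coding(system="urn:s", code="a"),
            m.Coding(system="urn:s", code="a", display="again"),
        ]
    )
    group = m.GroupResource(
        id="g", name="g", characteristics=[m.GroupCharacteristic(code=cc)]
    )
    issues = e.validate_resource(group)
    assert any("duplicate" in i.message for i in issues)


def test_attribute_estimate_invariants():
    bad = m.AttributeEstimate(
        type=m.CodeableConcept(text="ci"),
        level=1.5,
        range_low=m.Quantity(value=2.0),
        range_high=m.Quantity(value=1.0),
    )
    stat = m.Statistic(
        statistic_type=m.CodeableConcept(
            coding=[
                m.Coding(
                    system="urn:ebmkit:codesystem:statistic-type",
                    code="mean",
                )
            ]
        ),
        attribute_estimate=[bad],
    )
    ev = m.EvidenceResource(
        id="x",
        variable_definition=[
            m.VariableDefinition(
                variable_role="exposure", intended=m.Reference(target="E/1")
            )
        ],
        statistic=[stat],
    )
    messages = [i.message for i in e.validate_resource(ev)]
    assert any("level" in msg for msg in messages)
    assert any("low exceeds" in msg for msg in messages)


def test_certainty_nesting_depth_capped():
    deep = m.CertaintyRating(
        type=m.CodeableConcept(text="overall certainty"),
        rating=m.CodeableConcept(text="high"),
        subcomponents=[
            m.CertaintyRating(
                type=m.CodeableConcept(text="risk of bias"),
                rating=m.CodeableConcept(text="low"),
                subcomponents=[
                    m.CertaintyRating(
                        type=m.CodeableConcept(text="too deep"),
                        rating=m.CodeableConcept(text="low"),
                    )
                ],
            )
        ],
    )
    ev = m.EvidenceResource(
        id="x",
        variable_definition=[
            m.VariableDefinition(
                variable_role="exposure", intended=m.Reference(target="E/1")
            )
        ],
        certainty=[deep],
    )
    issues = e.validate_resource(ev, mode="lenient")
    assert any("depth" in i.message for i in issues)


def test_rating_quantity_only_for_ratings():
    aa = m.ArtifactAssessmentResource(
        id="a",
        content=[
            m.AssessmentContent(
                information_type="comment",
                rating_quantity=m.Quantity(value=3.0),
            )
        ],
    )
    issues = e.validate_resource(aa)
    assert any("rating" in i.message for i in issues)


def test_resource_type_of(walkthrough):
    assert e.resource_type_of(walkthrough.evidence[0]) == "Evidence"
    assert e.resource_type_of(walkthrough.groups[0]) == "Group"
    assert e.resource_type_of(walkthrough.citations[0]) == "Citation"
    with pytest.raises(UnknownResourceTypeError):
        e.resource_type_of({})
    with pytest.raises(UnknownResourceTypeError):
        e.resource_type_of(None)
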