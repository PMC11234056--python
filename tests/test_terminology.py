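"""Code systems, value sets, expansion, and membership classification."""

import numpy as np
import networkx as nx
import pytest

import ebmkit as e
from ebmkit import model as m
from ebmkit.errors import TerminologyError
from ebmkit.terminology import (
    CodeSystemDef,
    ConceptDef,
    Include,
    ValueSetDef,
    expand_value_set,
    validate_code,
)


def test_packaged_statistic_type_set_has_22_concepts(registry):
    triples = expand_value_set(registry.value_sets["statistic-type"], registry)
    assert len(triples) == 22
    displays = {d for _, _, d in triples}
    assert {"median", "relative risk", "incidence rate ratio"} <= displays


def test_certainty_aspects_are_the_nine(registry):
    cs = registry.systems["urn:ebmkit:codesystem:certainty-aspect"]
    assert {c.display for c in cs.concepts} == {
        "overall certainty",
        "risk of bias",
        "inconsistency",
        "indirectness",
        "imprecision",
        "publication bias",
        "dose-response gradient",
        "plausible confounding",
        "large effect size",
    }


def test_certainty_levels(registry):
    cs = registry.systems["urn:ebmkit:codesystem:certainty-rating"]
    assert [c.code for c in cs.concepts] == ["high", "moderate", "low", "very-low"]


def test_every_packaged_concept_has_code_and_display(registry):
    assert len(registry.systems) >= 4
    for cs in registry.systems.values():
        for concept in cs.concepts:
            assert concept.code and concept.display


def test_expansion_is_idempotent_and_sorted(registry):
    vs = registry.value_sets["certainty-rating"]
    first = expand_value_set(vs, registry)
    second = expand_value_set(vs, registry)
    assert first == second == sorted(first)


def test_empty_value_set_expands_empty(registry):
    assert expand_value_set(ValueSetDef(id="empty"), registry) == []


def test_unregistered_system_raises(registry):
    vs = ValueSetDef(id="x", includes=[Include(system_uri="urn:missing")])
    with pytest.raises(TerminologyError):
        expand_value_set(vs, registry)


def test_validate_code_states(registry):
    vs = registry.value_sets["certainty-aspect"]
    risk_of_bias = m.CodeableConcept(
        coding=[
            m.Coding(
                system="urn:ebmkit:codesystem:certainty-aspect",
                code="risk-of-bias",
                display="risk of bias",
            )
        ]
    )
    assert validate_code(risk_of_bias, vs, registry) == "valid"
    assert validate_code(m.CodeableConcept(), vs, registry) == "invalid"
    assert validate_code(
        m.CodeableConcept(text="risk of bias"), vs, registry
    ) == "text-only"
    wrong = m.CodeableConcept(coding=[m.Coding(system="urn:x", code="nope")])
    assert validate_code(wrong, vs, registry) == "invalid"


def _random_tree_system(rng: np.random.Generator, n: int = 50) -> CodeSystemDef:
    concepts = [ConceptDef(code="n0", display="n0")]
    for i in range(1, n):
        parent = f"n{int(rng.integers(0, i))}"
        concepts.append(ConceptDef(code=f"n{i}", display=f"n{i}", parent=parent))
    return CodeSystemDef(system_uri="urn:test:tree", title="tree", concepts=concepts)


@pytest.mark.parametrize("seed", range(5))
def test_descendants_match_graph_reachability_oracle(seed):
    rng = np.random.default_rng(seed)
    cs = _random_tree_system(rng)
    graph = nx.DiGraph()
    for c in cs.concepts:
        graph.add_node(c.code)
        if c.parent is not None:
            graph.add_edge(c.parent, c.code)
    registry = e.Registry()
    registry.register_system(cs)
    for root in ("n0", f"n{int(rng.integers(0, 50))}"):
        expected = set(nx.descendants(graph, root))
        vs = ValueSetDef(
            id="desc",
            includes=[
                Include(
                    system_uri=cs.system_uri,
                    mode="descendants-of",
                    codes=[root],
                )
            ],
        )
        got = {code for _, code, _ in expand_value_set(vs, registry)}
        assert got == expected
        vs.includes[0].include_root = True
        got_with_root = {code for _, code, _ in expand_value_set(vs, registry)}
        assert got_with_root == expected | {root}


@pytest.mark.parametrize("seed", range(5))
def test_membership_matches_linear_scan_oracle(seed, registry):
    rng = np.random.default_rng(100 + seed)
    uris = sorted(registry.systems)
    for _ in range(20):
        uri = uris[int(rng.integers(0, len(uris)))]
        cs = registry.systems[uri]
        codes = [c.code for c in cs.concepts]
        chosen = [codes[int(i)] for i in
                  rng.choice(len(codes), size=min(3, len(codes)), replace=False)]
        vs = ValueSetDef(
            id="rand",
            includes=[Include(system_uri=uri, mode="listed-codes", codes=chosen)],
        )
        probe_code = codes[int(rng.integers(0, len(codes)))]
        concept = m.CodeableConcept(
            coding=[m.Coding(system=uri, code=probe_code)]
        )
        expected = "valid" if probe_code in chosen else "invalid"
        assert validate_code(concept, vs, registry) == expected


def test_cycle_and_duplicate_detection():
    with pytest.raises(TerminologyError, match="cycle"):
        CodeSystemDef(
            system_uri="urn:t",
            title="t",
            concepts=[
                ConceptDef(code="a", display="a", parent="b"),
                ConceptDef(code="b", display="b", parent="a"),
            ],
        )
    with pytest.raises(TerminologyError, match="duplicate"):
        CodeSystemDef(
            system_uri="urn:t",
            title="t",
            concepts=[
                ConceptDef(code="a", display="a"),
                ConceptDef(code="a", display="again"),
            ],
        )
    with pytest.raises(TerminologyError, match="parent"):
        CodeSystemDef(
            system_uri="urn:t",
            title="t",
            concepts=[ConceptDef(code="a", display="a", parent="ghost")],
        )
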