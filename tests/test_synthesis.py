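"""Signature matching, grouping, and inverse-variance pooling."""

import copy
import math

import numpy as np
import pytest

import ebmkit as e
from ebmkit import model as m
from ebmkit.errors import BundleError, SynthesisError
from ebmkit.io import Resolver
from tests.conftest import random_estimate


def brute_force_pool(thetas, variances, model):
    """Independent inverse-variance oracle with explicit sums."""
    k = len(thetas)
    weights = [1.0 / v for v in variances]
    s1 = 0.0
    for w in weights:
        s1 += w
    num = 0.0
    for w, t in zip(weights, thetas):
        num += w * t
    fixed = num / s1
    q = 0.0
    for w, t in zip(weights, thetas):
        q += w * (t - fixed) ** 2
    tau2 = 0.0
    if model == "random" and k > 1:
        s2 = 0.0
        for w in weights:
            s2 += w * w
        c = s1 - s2 / s1
        if c > 0:
            tau2 = max(0.0, (q - (k - 1)) / c)
    if model == "random":
        weights = [1.0 / (v + tau2) for v in variances]
    sw = 0.0
    num = 0.0
    for w, t in zip(weights, thetas):
        sw += w
        num += w * t
    return num / sw, math.sqrt(1.0 / sw), q, tau2


# ---------------------------------------------------------------------------
# Signatures and grouping
# ---------------------------------------------------------------------------


def test_identical_evidence_same_signature(walkthrough, walkthrough_resolver):
    ev = walkthrough.evidence[0]
    twin = copy.deepcopy(ev)
    assert e.signature_of(ev, walkthrough_resolver) == e.signature_of(
        twin, walkthrough_resolver
    )


def test_signature_insensitive_to_coding_order(walkthrough):
    resources = walkthrough.resources
    shuffled = copy.deepcopy(resources)
    for r in shuffled:
        if isinstance(r, m.EvidenceVariableResource) and r.definition:
            r.definition.coding = list(reversed(r.definition.coding))
            r.definition.coding.append(
                m.Coding(system="urn:extra", code="alias")
            )
    # extra codings change the signature; pure reordering must not
    reordered = copy.deepcopy(resources)
    for r in reordered:
        if isinstance(r, m.EvidenceVariableResource) and r.definition:
            r.definition.coding = list(reversed(r.definition.coding))
            for c in r.definition.coding:
                c.display = (c.display or "").upper()  # display is ignored
    ev = walkthrough.evidence[0]
    sig_orig = e.signature_of(ev, Resolver(resources))
    sig_reord = e.signature_of(ev, Resolver(reordered))
    sig_extra = e.signature_of(ev, Resolver(shuffled))
    assert sig_orig == sig_reord
    assert sig_orig != sig_extra


def test_changed_outcome_changes_signature(walkthrough):
    resources = copy.deepcopy(walkthrough.resources)
    for r in resources:
        if r.id == "walkthrough-variable-outcome":
            r.definition.coding[0].code = "different-outcome"
    ev = walkthrough.evidence[0]
    assert e.signature_of(ev, Resolver(resources)) != e.signature_of(
        ev, Resolver(walkthrough.resources)
    )


def test_text_only_definitions_match_after_normalization():
    def variable(vid, text):
        return m.EvidenceVariableResource(
            id=vid, name=None, definition=m.CodeableConcept(text=text)
        )

    def evidence(eid, target):
        return m.EvidenceResource(
            id=eid,
            variable_definition=[
                m.VariableDefinition(
                    variable_role="measured-variable",
                    intended=m.Reference(target=target),
                )
            ],
        )

    va = variable("v1", "All-Cause   Mortality")
    vb = variable("v2", "all-cause mortality")
    ev_a = evidence("e1", "EvidenceVariable/v1")
    ev_b = evidence("e2", "EvidenceVariable/v2")
    resolver = Resolver([va, vb])
    assert e.signature_of(ev_a, resolver) == e.signature_of(ev_b, resolver)


def test_unresolvable_reference_names_target(walkthrough):
    ev = copy.deepcopy(walkthrough.evidence[0])
    ev.variable_definition[0].intended = m.Reference(target="EvidenceVariable/ghost")
    ev.variable_definition[0].observed = None
    with pytest.raises(BundleError, match="ghost"):
        e.signature_of(ev, Resolver(walkthrough.resources))


def test_group_comparable_partition():
    bundle_a = e.simulate_evidence_set(e.SimulationConfig(k=3, seed=1))
    bundle_b = e.simulate_evidence_set(e.SimulationConfig(k=3, seed=2))
    # second signature: rename shared variable ids and codes
    for r in bundle_b:
        r.id = r.id.replace("sim-", "alt-")
        if isinstance(r, m.EvidenceVariableResource) and r.definition:
            for c in r.definition.coding:
                c.code = f"alt-{c.code}"
        if isinstance(r, m.GroupResource):
            for ch in r.characteristics:
                for c in ch.code.coding:
                    c.code = f"alt-{c.code}"
        if isinstance(r, m.EvidenceResource):
            for vd in r.variable_definition:
                for ref in (vd.observed, vd.intended):
                    if ref is not None:
                        ref.target = ref.target.replace("sim-", "alt-")
    resources = bundle_a + bundle_b
    resolver = Resolver(resources)
    evidence = [r for r in resources if isinstance(r, m.EvidenceResource)]
    blocks = e.group_comparable(evidence, resolver)
    assert [len(b) for b in blocks] == [3, 3]
    assert e.group_comparable([], resolver) == []
    assert [len(b) for b in e.group_comparable(evidence[:1], resolver)] == [1]


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def test_pool_single_study_is_identity():
    rng = np.random.default_rng(3)
    est = random_estimate(rng)
    result = e.pool([est], model="fixed")
    assert result.k == 1
    assert result.Q == 0.0
    assert result.I2 == 0.0
    assert result.pooled.point == pytest.approx(est.point, rel=1e-12)


def test_pool_identical_studies():
    rng = np.random.default_rng(4)
    est = random_estimate(rng)
    block = [copy.deepcopy(est) for _ in range(3)]
    fixed = e.pool(block, model="fixed")
    random = e.pool(block, model="random")
    assert fixed.Q == pytest.approx(0.0, abs=1e-18)
    assert fixed.pooled.point == pytest.approx(est.point, rel=1e-12)
    assert random.tau2 == 0.0
    assert random.pooled.point == pytest.approx(fixed.pooled.point, rel=1e-12)
    assert random.pooled.se == pytest.approx(fixed.pooled.se, rel=1e-12)


@pytest.mark.parametrize("model", ["fixed", "random"])
def test_pool_matches_brute_force_oracle(model):
    rng = np.random.default_rng(5)
    for _ in range(100):
        block = [random_estimate(rng) for _ in range(5)]
        result = e.pool(block, model=model)
        theta, se, q, tau2 = brute_force_pool(
            [math.log(b.point) for b in block],
            [b.se**2 for b in block],
            model,
        )
        assert math.log(result.pooled.point) == pytest.approx(theta, abs=1e-10)
        assert result.pooled.se == pytest.approx(se, abs=1e-10)
        assert result.Q == pytest.approx(q, abs=1e-10)
        assert result.tau2 == pytest.approx(tau2, abs=1e-10)
        assert sum(result.weights) == pytest.approx(1.0, abs=1e-9)
        assert result.Q >= 0 and 0 <= result.I2 < 1 and result.tau2 >= 0


def test_pool_matches_statsmodels():
    from statsmodels.stats.meta_analysis import combine_effects

    rng = np.random.default_rng(6)
    # heterogeneous block so the DL tau2 is positive (statsmodels does not
    # truncate negative moment estimates; comparison is only fair above 0)
    thetas = [0.1, 0.9, -0.5, 1.2, 0.0]
    ses = [0.15, 0.2, 0.25, 0.2, 0.3]
    block = []
    for t, s in zip(thetas, ses):
        est = random_estimate(rng)
        est.point = math.exp(t)
        est.se = s
        block.append(est)
    sm = combine_effects(np.array(thetas), np.array(ses) ** 2, method_re="dl")
    fixed = e.pool(block, model="fixed")
    random = e.pool(block, model="random")
    assert math.log(fixed.pooled.point) == pytest.approx(
        sm.mean_effect_fe, rel=1e-10
    )
    assert random.tau2 == pytest.approx(sm.tau2, rel=1e-10)
    assert math.log(random.pooled.point) == pytest.approx(
        sm.mean_effect_re, rel=1e-10
    )
    assert fixed.Q == pytest.approx(sm.q, rel=1e-10)


def test_pooled_point_is_convex_combination():
    rng = np.random.default_rng(8)
    for _ in range(20):
        block = [random_estimate(rng) for _ in range(4)]
        result = e.pool(block, model="fixed")
        points = [b.analysis_point for b in block]
        assert min(points) <= result.pooled.analysis_point <= max(points)


def test_pool_order_invariance():
    rng = np.random.default_rng(9)
    block = [random_estimate(rng) for _ in range(6)]
    forward = e.pool(block, model="random")
    backward = e.pool(block[::-1], model="random")
    assert forward.pooled.point == pytest.approx(backward.pooled.point, rel=1e-12)
    assert forward.tau2 == pytest.approx(backward.tau2, rel=1e-12)


def test_pool_error_cases():
    rng = np.random.default_rng(10)
    with pytest.raises(SynthesisError):
        e.pool([], model="fixed")
    mixed = [random_estimate(rng, "odds-ratio"), random_estimate(rng, "risk-ratio")]
    with pytest.raises(SynthesisError, match="mixed"):
        e.pool(mixed)
    no_se = random_estimate(rng)
    no_se.se = None
    with pytest.raises(SynthesisError, match="standard error"):
        e.pool([no_se])


# ---------------------------------------------------------------------------
# Pooled Evidence emission
# ---------------------------------------------------------------------------


def test_pooled_to_evidence_fields(walkthrough, walkthrough_resolver):
    rng = np.random.default_rng(11)
    block = [random_estimate(rng) for _ in range(3)]
    result = e.pool(block, model="fixed")
    sig = e.signature_of(walkthrough.evidence[0], walkthrough_resolver)
    pooled = e.pooled_to_evidence(result, signature=sig)
    assert pooled.statistic[0].sample_size.number_of_studies == 3
    codes = [
        c.code
        for mc in pooled.statistic[0].model_characteristic
        for c in mc.code.coding
    ]
    assert "fixed-effect" in codes
    assert e.validate_resource(pooled, mode="strict") == []


def test_random_effects_evidence_carries_tau2():
    rng = np.random.default_rng(12)
    block = [random_estimate(rng) for _ in range(5)]
    result = e.pool(block, model="random")
    pooled = e.pooled_to_evidence(result)
    tau2_values = [
        mc.value.value
        for mc in pooled.statistic[0].model_characteristic
        if any(c.code == "between-study-variance" for c in mc.code.coding)
    ]
    assert tau2_values == [pytest.approx(result.tau2)]
    assert e.validate_resource(pooled, mode="strict") == []
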