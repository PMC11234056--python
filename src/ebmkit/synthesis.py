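"""Grouping comparable Evidence and inverse-variance meta-analysis.

Two Evidence resources are comparable when their variable definitions
resolve to the same concepts, role by role.  :func:`signature_of` builds a
canonical signature -- insensitive to Coding order, display text, and
letter case -- and :func:`group_comparable` partitions a bundle by it.

Pooling is inverse-variance on the analysis scale (log for ratio
measures).  The fixed-effect weight of study *i* is ``w_i = 1/v_i``; the
random-effects model uses the DerSimonian-Laird moment estimator

    tau^2 = max(0, (Q - df) / (S1 - S2/S1)),   S1 = sum w_i, S2 = sum w_i^2

with re-weighting ``w*_i = 1/(v_i + tau^2)``.  Heterogeneity is summarized
by Cochran's Q (weighted sum of squared deviations from the fixed-effect
estimate) and ``I^2 = max(0, (Q - df)/Q)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Union

from . import model as m
from .errors import BundleError, SynthesisError
from .statistics import EffectEstimate, LOG_SCALE_MEASURES, _z
from .terminology import SYSTEM_URI

__all__ = [
    "VariableSignature",
    "MetaAnalysisResult",
    "signature_of",
    "group_comparable",
    "pool",
    "pooled_to_evidence",
]

ResolverLike = Union["object", Callable[[m.Reference], m.AnyResource]]


def _normalize_text(text: str) -> str:
    return " ".join(text.lower().split())


@dataclass(frozen=True)
class VariableSignature:
    """Canonical, order-insensitive content of an Evidence's variables.

    ``role_to_keys`` maps each variable role to a frozenset of concept keys:
    ``("code", system, code)`` tuples from codings, falling back to
    ``("text", normalized-text)`` when a variable is defined by text only.
    """

    role_to_keys: frozenset  # frozenset of (role, frozenset-of-keys)
    representative_refs: tuple = field(compare=False, hash=False, default=())

    def roles(self) -> set[str]:
        return {role for role, _ in self.role_to_keys}


def _concept_keys_for(resource: m.AnyResource) -> frozenset:
    """Concept keys describing an EvidenceVariable or Group resource."""
    keys: set[tuple] = set()
    texts: set[str] = set()
    if isinstance(resource, m.EvidenceVariableResource):
        if resource.definition is not None:
            for coding in resource.definition.coding:
                if coding.code is not None:
                    keys.add(("code", coding.system, coding.code))
            if resource.definition.text:
                texts.add(resource.definition.text)
        if not keys:
            for t in (resource.name, resource.description):
                if t:
                    texts.add(t)
                    break
    elif isinstance(resource, m.GroupResource):
        for ch in resource.characteristics:
            for coding in ch.code.coding:
                if coding.code is not None:
                    keys.add(("code", coding.system, coding.code))
            if isinstance(ch.value, m.CodeableConcept):
                for coding in ch.value.coding:
                    if coding.code is not None:
                        keys.add(("code", coding.system, coding.code))
        if not keys:
            if resource.name:
                texts.add(resource.name)
            for ch in resource.characteristics:
                if ch.code.text:
                    texts.add(ch.code.text)
    else:
        raise SynthesisError(
            f"variable reference resolves to a {type(resource).__name__}, "
            "expected EvidenceVariable or Group"
        )
    if keys:  # coded concepts take precedence over text
        return frozenset(keys)
    return frozenset(("text", _normalize_text(t)) for t in texts)


def _resolve(resolver: ResolverLike, ref: m.Reference) -> m.AnyResource:
    if resolver is None:
        raise BundleError(f"no resolver provided for reference {ref.target!r}")
    if callable(resolver) and not hasattr(resolver, "resolve"):
        return resolver(ref)
    return resolver.resolve(ref)


def signature_of(
    evidence: m.EvidenceResource,
    resolver: ResolverLike,
    require_both: bool = False,
) -> VariableSignature:
    """Build the matching signature of one Evidence resource.

    For each variable definition the ``intended`` reference is used when
    present, else ``observed`` (set ``require_both`` to demand both resolve
    to the same concepts).  Unresolvable references raise
    :class:`~ebmkit.errors.BundleError` naming the target.
    """
    pairs: dict[str, set] = {}
    refs: dict[str, m.Reference] = {}
    for vd in evidence.variable_definition:
        chosen = vd.intended if vd.intended is not None else vd.observed
        if chosen is None:
            continue
        keys = _concept_keys_for(_resolve(resolver, chosen))
        if require_both and vd.intended is not None and vd.observed is not None:
            observed_keys = _concept_keys_for(_resolve(resolver, vd.observed))
            if observed_keys != keys:
                raise SynthesisError(
                    f"intended and observed variables disagree for role "
                    f"{vd.variable_role!r}"
                )
        pairs.setdefault(vd.variable_role, set()).update(keys)
        refs.setdefault(vd.variable_role, chosen)
    return VariableSignature(
        role_to_keys=frozenset(
            (role, frozenset(keys)) for role, keys in pairs.items()
        ),
        representative_refs=tuple(sorted(refs.items(), key=lambda kv: kv[0])),
    )


def group_comparable(
    evidence: Iterable[m.EvidenceResource], resolver: ResolverLike
) -> list[list[m.EvidenceResource]]:
    """Partition Evidence resources into maximal comparable blocks.

    Blocks and their members keep first-seen order, so the partition is
    stable under re-runs.
    """
    blocks: dict[VariableSignature, list[m.EvidenceResource]] = {}
    for ev in evidence:
        sig = signature_of(ev, resolver)
        blocks.setdefault(sig, []).append(ev)
    return list(blocks.values())


@dataclass
class MetaAnalysisResult:
    """Pooled effect with weights and heterogeneity summaries."""

    model: str  # "fixed" | "random"
    pooled: EffectEstimate
    weights: list[float]  # normalized, sum to 1
    Q: float
    df: int
    I2: float
    tau2: float
    k: int


def pool(
    block: list[EffectEstimate],
    model: str = "fixed",
    ci_level: float = 0.95,
) -> MetaAnalysisResult:
    """Inverse-variance pooling of a block of comparable estimates.

    All estimates must share one measure and carry a standard error.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    if not block:
        raise SynthesisError("cannot pool an empty block")
    measures = {e.measure for e in block}
    if len(measures) != 1:
        raise SynthesisError(f"mixed measures in block: {sorted(measures)}")
    measure = measures.pop()
    for i, e in enumerate(block):
        if e.se is None or e.se <= 0:
            raise SynthesisError(f"estimate {i} has no usable standard error")
    log_scale = measure in LOG_SCALE_MEASURES
    theta = [e.analysis_point for e in block]
    v = [e.se**2 for e in block]
    w = [1.0 / vi for vi in v]
    k = len(block)
    s1 = sum(w)
    theta_fixed = sum(wi * ti for wi, ti in zip(w, theta)) / s1
    Q = sum(wi * (ti - theta_fixed) ** 2 for wi, ti in zip(w, theta))
    df = k - 1
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0

    tau2 = 0.0
    if model == "random" and k > 1:
        s2 = sum(wi**2 for wi in w)
        denom = s1 - s2 / s1
        if denom > 0:
            tau2 = max(0.0, (Q - df) / denom)
    if model == "random":
        w_used = [1.0 / (vi + tau2) for vi in v]
    else:
        w_used = w
    sw = sum(w_used)
    theta_pooled = sum(wi * ti for wi, ti in zip(w_used, theta)) / sw
    se_pooled = math.sqrt(1.0 / sw)
    z = _z(ci_level)
    lo, hi = theta_pooled - z * se_pooled, theta_pooled + z * se_pooled
    if log_scale:
        point, lo, hi = math.exp(theta_pooled), math.exp(lo), math.exp(hi)
    else:
        point = theta_pooled
    pooled = EffectEstimate(
        measure=measure,
        point=point,
        se=se_pooled,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        events=sum(e.events for e in block)
        if all(e.events is not None for e in block)
        else None,
        total=sum(e.total for e in block)
        if all(e.total is not None for e in block)
        else None,
    )
    return MetaAnalysisResult(
        model=model,
        pooled=pooled,
        weights=[wi / sw for wi in w_used],
        Q=Q,
        df=df,
        I2=I2,
        tau2=tau2,
        k=k,
    )


_MODEL_SYSTEM = SYSTEM_URI["statistical-model"]
_AE_SYSTEM = SYSTEM_URI["attribute-estimate-type"]


def _model_code(code: str, display: str) -> m.CodeableConcept:
    return m.CodeableConcept(
        coding=[m.Coding(system=_MODEL_SYSTEM, code=code, display=display)]
    )


def pooled_to_evidence(
    r: MetaAnalysisResult,
    signature: Optional[VariableSignature] = None,
    source_references: Iterable[m.Reference] = (),
    evidence_id: str = "pooled-evidence",
) -> m.EvidenceResource:
    """Express a meta-analysis result as an Evidence resource.

    The pooled statistic carries ``sampleSize.numberOfStudies = k``, a
    model characteristic coding the pooling model (plus the between-study
    variance for a random-effects pool), and attribute estimates for the
    interval, Cochran's Q, and I^2.
    """
    from .statistics import to_statistic  # deferred: shared helpers

    sources = list(source_references)
    sample = m.SampleSize(
        number_of_studies=r.k,
        total_participants=r.pooled.total,
        known_data_count=r.pooled.total,
    )
    stat = to_statistic(
        r.pooled,
        sample=sample,
        description=f"{r.model}-effect{'s' if r.model == 'random' else ''} "
        f"pooled estimate over {r.k} studies",
    )
    stat.number_of_events = r.pooled.events
    stat.attribute_estimate.extend(
        [
            m.AttributeEstimate(
                type=m.CodeableConcept(
                    coding=[
                        m.Coding(
                            system=_AE_SYSTEM, code="cochran-q", display="Cochran's Q"
                        )
                    ]
                ),
                quantity=m.Quantity(value=r.Q),
            ),
            m.AttributeEstimate(
                type=m.CodeableConcept(
                    coding=[
                        m.Coding(
                            system=_AE_SYSTEM, code="i-squared", display="I-squared"
                        )
                    ]
                ),
                quantity=m.Quantity(value=r.I2),
            ),
        ]
    )
    model_code = (
        _model_code("fixed-effect", "fixed-effect inverse-variance")
        if r.model == "fixed"
        else _model_code("random-effects", "random-effects (DerSimonian-Laird)")
    )
    stat.model_characteristic.append(m.ModelCharacteristic(code=model_code))
    if r.model == "random":
        stat.model_characteristic.append(
            m.ModelCharacteristic(
                code=_model_code("between-study-variance", "between-study variance"),
                value=m.Quantity(value=r.tau2),
            )
        )
    variable_definitions: list[m.VariableDefinition] = []
    if signature is not None:
        for role, ref in signature.representative_refs:
            variable_definitions.append(
                m.VariableDefinition(variable_role=role, intended=ref)
            )
    if not variable_definitions:
        # keep the resource strict-valid even without a signature
        variable_definitions.append(
            m.VariableDefinition(
                variable_role="measured-variable",
                description="pooled outcome",
                intended=m.Reference(target="EvidenceVariable/pooled-outcome"),
            )
        )
    description = (
        f"Pooled {r.pooled.measure} over {r.k} studies"
        + (
            " from " + ", ".join(ref.target for ref in sources)
            if sources
            else ""
        )
    )
    return m.EvidenceResource(
        id=evidence_id,
        title=f"Pooled evidence ({r.model} effect, k={r.k})",
        description=description,
        variable_definition=variable_definitions,
        statistic=[stat],
    )
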