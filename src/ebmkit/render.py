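"""Human-readable text rendering of resources and bundles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from . import model as m
from .io import ParseReport
from .statistics import render_percent

__all__ = ["RenderedSummary", "render"]


@dataclass
class RenderedSummary:
    """Deterministic text lines summarizing one resource or a bundle."""

    lines: list[str] = field(default_factory=list)

    @property
    def text(self) -> str:
        return "\n".join(self.lines)

    def __str__(self) -> str:
        return self.text


def _fmt(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return f"{x:g}"


def _interval_label(cc: m.CodeableConcept) -> str:
    for coding in cc.coding:
        if coding.code == "credible-interval":
            return "credible interval"
        if coding.code == "confidence-interval":
            return "confidence interval"
    return cc.text or "interval"


def _statistic_lines(s: m.Statistic) -> list[str]:
    label = None
    for coding in s.statistic_type.coding:
        if coding.display:
            label = coding.display
            break
    label = label or s.statistic_type.text or "statistic"
    parts = [label]
    if s.quantity is not None:
        parts.append(_fmt(s.quantity.value))
    interval_part = ""
    extras = []
    for ae in s.attribute_estimate:
        if ae.range_low is not None and ae.range_high is not None:
            level = f"{ae.level * 100:g}% " if ae.level is not None else ""
            interval_part = (
                f" ({level}{_interval_label(ae.type)} "
                f"{_fmt(ae.range_low.value)}–{_fmt(ae.range_high.value)})"
            )
        elif ae.quantity is not None:
            name = None
            for coding in ae.type.coding:
                name = coding.display or coding.code
                break
            name = name or ae.type.text or "attribute"
            extras.append(f"{name} {_fmt(ae.quantity.value)}")
    line = "  " + " ".join(parts) + interval_part
    lines = [line]
    if s.sample_size is not None and s.sample_size.number_of_studies not in (None, 1):
        lines.append(f"    studies: {s.sample_size.number_of_studies}")
    if extras:
        lines.append("    " + "; ".join(extras))
    if s.description:
        lines.append(f"    {s.description}")
    return lines


def _certainty_lines(c: m.CertaintyRating, indent: str = "  ") -> list[str]:
    aspect = c.type.text or next(
        (x.display or x.code for x in c.type.coding), "certainty"
    )
    rating = c.rating.text or next(
        (x.display or x.code for x in c.rating.coding), "?"
    )
    lines = [f"{indent}certainty ({aspect}): {rating}"]
    for sub in c.subcomponents:
        lines.extend(_certainty_lines(sub, indent + "  "))
    return lines


def _render_evidence(r: m.EvidenceResource) -> list[str]:
    lines = [f"Evidence {r.id}: {r.title or r.description or ''}".rstrip()]
    for vd in r.variable_definition:
        target = (vd.intended or vd.observed)
        where = f" -> {target.target}" if target else ""
        desc = f" ({vd.description})" if vd.description else ""
        lines.append(f"  {vd.variable_role}{desc}{where}")
    for s in r.statistic:
        lines.extend(_statistic_lines(s))
    for c in r.certainty:
        lines.extend(_certainty_lines(c))
    return lines


def _render_group(r: m.GroupResource) -> list[str]:
    lines = [f"Group {r.id}: {r.name or ''}".rstrip()]
    if r.member_count is not None:
        lines.append(f"  members: {r.member_count}")
    for ch in r.characteristics:
        label = ch.code.text or next(
            (c.display or c.code for c in ch.code.coding), "characteristic"
        )
        if isinstance(ch.value, m.Quantity):
            value = int(ch.value.value) if ch.value.value == int(
                ch.value.value
            ) else ch.value.value
            line = f"  {label}: {value}"
            if r.member_count:
                pct = render_percent(ch.value.value / r.member_count)
                line = f"  {label}: {value}/{r.member_count} ({pct})"
            lines.append(line)
        elif isinstance(ch.value, m.CodeableConcept):
            value_label = ch.value.text or next(
                (c.display or c.code for c in ch.value.coding), ""
            )
            lines.append(f"  {label}: {value_label}")
        else:
            lines.append(f"  {label}")
    return lines


def _render_evidence_variable(r: m.EvidenceVariableResource) -> list[str]:
    lines = [f"EvidenceVariable {r.id}: {r.name or ''}".rstrip()]
    if r.handling:
        lines.append(f"  handling: {r.handling}")
    if r.definition is not None and r.definition.coding:
        c = r.definition.coding[0]
        lines.append(f"  definition: {c.display or c.code}")
    elif r.description:
        lines.append(f"  definition: {r.description}")
    return lines


def _render_citation(r: m.CitationResource) -> list[str]:
    ca = r.cited_artifact
    lines = [f"Citation {r.id}: {ca.title or r.summary or ''}".rstrip()]
    if ca.contributorship:
        names = "; ".join(c.name for c in ca.contributorship)
        lines.append(f"  authors: {names}")
    pf = ca.publication_form
    if pf is not None and (pf.published_in_title or pf.date):
        bits = [b for b in (pf.published_in_title, pf.date) if b]
        detail = ", ".join(bits)
        if pf.volume:
            detail += f"; {pf.volume}"
            if pf.issue:
                detail += f"({pf.issue})"
            if pf.first_page:
                detail += f":{pf.first_page}"
                if pf.last_page:
                    detail += f"-{pf.last_page}"
        lines.append(f"  published in: {detail}")
    for ident in ca.identifiers:
        lines.append(f"  {ident.type}: {ident.value}")
    return lines


def _render_artifact_assessment(r: m.ArtifactAssessmentResource) -> list[str]:
    target = (
        r.artifact.target if isinstance(r.artifact, m.Reference) else r.artifact
    )
    lines = [f"ArtifactAssessment {r.id}: about {target or '?'}"]
    for c in r.content:
        bits = [c.information_type]
        if c.rating_quantity is not None:
            bits.append(_fmt(c.rating_quantity.value))
        if c.author:
            bits.append(f"by {c.author}")
        lines.append("  " + " ".join(bits))
    return lines


_RENDERERS = {
    m.EvidenceResource: _render_evidence,
    m.GroupResource: _render_group,
    m.EvidenceVariableResource: _render_evidence_variable,
    m.CitationResource: _render_citation,
    m.ArtifactAssessmentResource: _render_artifact_assessment,
}


def render(
    target: Union[m.AnyResource, ParseReport, Iterable]
) -> RenderedSummary:
    """Render one resource, a ParseReport, or an iterable of either."""
    if isinstance(target, ParseReport):
        target = target.resource
    renderer = _RENDERERS.get(type(target))
    if renderer is not None:
        return RenderedSummary(lines=renderer(target))
    resources = [
        t.resource if isinstance(t, ParseReport) else t for t in target
    ]
    lines = [f"{len(resources)} resources"]
    for r in resources:
        lines.append("")
        lines.extend(_RENDERERS[type(r)](r))
    return RenderedSummary(lines=lines)
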