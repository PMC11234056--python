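"""Controlled terminologies: code systems, value sets, expansion, membership.

Code systems are flat-or-hierarchical concept lists (each concept may name a
parent within the same system); value sets compose selections over one or
more registered systems with three include modes:

``all``
    every concept of the system;
``listed-codes``
    an explicit enumeration;
``descendants-of``
    the full transitive closure below each listed root (the root itself is
    excluded unless the include sets ``include_root``).

The packaged registry ships the code sets the evidence model binds to:
statistic types (a 22-code value set), the nine certainty aspects, the four
GRADE-style certainty levels plus modifier codes, the six variable roles,
attribute-estimate types, statistical-model codes, and small representative
stubs for study design and risk of bias.  System URIs are project-local URNs
so no external terminology is impersonated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import TerminologyError
from .model import CodeableConcept

__all__ = [
    "ConceptDef",
    "CodeSystemDef",
    "Include",
    "ValueSetDef",
    "Registry",
    "expand_value_set",
    "validate_code",
    "load_code_system",
    "load_value_set",
    "load_packaged_terminologies",
    "SYSTEM_URI",
]

#: URIs of the packaged code systems, keyed by short name.
SYSTEM_URI = {
    "statistic-type": "urn:ebmkit:codesystem:statistic-type",
    "certainty-aspect": "urn:ebmkit:codesystem:certainty-aspect",
    "certainty-rating": "urn:ebmkit:codesystem:certainty-rating",
    "certainty-modifier": "urn:ebmkit:codesystem:certainty-modifier",
    "variable-role": "urn:ebmkit:codesystem:variable-role",
    "attribute-estimate-type": "urn:ebmkit:codesystem:attribute-estimate-type",
    "statistical-model": "urn:ebmkit:codesystem:statistical-model",
    "study-design": "urn:ebmkit:codesystem:study-design",
    "risk-of-bias": "urn:ebmkit:codesystem:risk-of-bias",
}


@dataclass
class ConceptDef:
    code: str
    display: str
    definition: Optional[str] = None
    parent: Optional[str] = None


@dataclass
class CodeSystemDef:
    """A code system: unique codes, optional single-parent hierarchy."""

    system_uri: str
    title: str
    concepts: list[ConceptDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        if not self.system_uri:
            raise TerminologyError("code system has an empty system URI")
        seen: set[str] = set()
        for c in self.concepts:
            if c.code in seen:
                raise TerminologyError(
                    f"duplicate code {c.code!r} in {self.system_uri}"
                )
            seen.add(c.code)
        for c in self.concepts:
            if c.parent is not None and c.parent not in seen:
                raise TerminologyError(
                    f"parent {c.parent!r} of {c.code!r} not defined "
                    f"in {self.system_uri}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {c.code: c.parent for c in self.concepts}
        for start in parent:
            slow = start
            seen_path: set[str] = set()
            while slow is not None:
                if slow in seen_path:
                    raise TerminologyError(
                        f"hierarchy cycle through {slow!r} in {self.system_uri}"
                    )
                seen_path.add(slow)
                slow = parent.get(slow)

    def concept(self, code: str) -> Optional[ConceptDef]:
        for c in self.concepts:
            if c.code == code:
                return c
        return None

    def children_map(self) -> dict[str, list[str]]:
        kids: dict[str, list[str]] = {}
        for c in self.concepts:
            if c.parent is not None:
                kids.setdefault(c.parent, []).append(c.code)
        return kids

    def descendants_of(self, root: str) -> set[str]:
        """All codes strictly below ``root`` (transitive closure)."""
        if self.concept(root) is None:
            raise TerminologyError(
                f"code {root!r} not defined in {self.system_uri}"
            )
        kids = self.children_map()
        out: set[str] = set()
        frontier = list(kids.get(root, []))
        while frontier:
            code = frontier.pop()
            if code not in out:
                out.add(code)
                frontier.extend(kids.get(code, []))
        return out


@dataclass
class Include:
    system_uri: str
    mode: str = "all"  # all | listed-codes | descendants-of
    codes: list[str] = field(default_factory=list)
    include_root: bool = False


@dataclass
class ValueSetDef:
    id: str
    includes: list[Include] = field(default_factory=list)


class Registry:
    """A collection of registered code systems and value sets."""

    def __init__(self) -> None:
        self.systems: dict[str, CodeSystemDef] = {}
        self.value_sets: dict[str, ValueSetDef] = {}

    def register_system(self, cs: CodeSystemDef) -> None:
        cs.check()
        self.systems[cs.system_uri] = cs

    def register_value_set(self, vs: ValueSetDef) -> None:
        self.value_sets[vs.id] = vs

    def system(self, uri: str) -> CodeSystemDef:
        try:
            return self.systems[uri]
        except KeyError:
            raise TerminologyError(f"system {uri!r} is not registered") from None


def expand_value_set(
    vs: ValueSetDef, registry: Registry
) -> list[tuple[str, str, str]]:
    """Expand a value set to ``(system, code, display)`` triples.

    The result is deduplicated and sorted by (system, code), so expansion is
    idempotent and order-deterministic regardless of include order.
    """
    out: dict[tuple[str, str], str] = {}
    for inc in vs.includes:
        cs = registry.system(inc.system_uri)
        if inc.mode == "all":
            selected: Iterable[str] = (c.code for c in cs.concepts)
        elif inc.mode == "listed-codes":
            for code in inc.codes:
                if cs.concept(code) is None:
                    raise TerminologyError(
                        f"listed code {code!r} not in {inc.system_uri}"
                    )
            selected = inc.codes
        elif inc.mode == "descendants-of":
            codes: set[str] = set()
            for root in inc.codes:
                codes |= cs.descendants_of(root)
                if inc.include_root:
                    codes.add(root)
            selected = codes
        else:
            raise TerminologyError(f"unknown include mode {inc.mode!r}")
        for code in selected:
            concept = cs.concept(code)
            out[(cs.system_uri, code)] = concept.display if concept else code
    return sorted((s, c, d) for (s, c), d in out.items())


def validate_code(
    concept: CodeableConcept, vs: ValueSetDef, registry: Registry
) -> str:
    """Classify a concept against a value set.

    Returns ``"valid"`` if any Coding is in the expansion, ``"text-only"``
    if the concept has no codings but carries text, else ``"invalid"``.
    """
    if not concept.coding:
        return "text-only" if concept.text else "invalid"
    members = {(s, c) for s, c, _ in expand_value_set(vs, registry)}
    for coding in concept.coding:
        if (coding.system, coding.code) in members:
            return "valid"
    return "invalid"


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _concepts_from_json(items: list[dict]) -> list[ConceptDef]:
    return [
        ConceptDef(
            code=i["code"],
            display=i["display"],
            definition=i.get("definition"),
            parent=i.get("parent"),
        )
        for i in items
    ]


def load_code_system(source: Union[str, Path, dict]) -> CodeSystemDef:
    """Load a code system from a JSON file or an already-parsed dict."""
    doc = source if isinstance(source, dict) else json.loads(
        Path(source).read_text(encoding="utf-8")
    )
    try:
        return CodeSystemDef(
            system_uri=doc["system"],
            title=doc.get("title", doc["system"]),
            concepts=_concepts_from_json(doc.get("concept", [])),
        )
    except KeyError as exc:
        raise TerminologyError(f"code-system document missing {exc}") from None


def load_value_set(source: Union[str, Path, dict]) -> ValueSetDef:
    doc = source if isinstance(source, dict) else json.loads(
        Path(source).read_text(encoding="utf-8")
    )
    try:
        return ValueSetDef(
            id=doc["id"],
            includes=[
                Include(
                    system_uri=i["system"],
                    mode=i.get("mode", "all"),
                    codes=list(i.get("codes", [])),
                    include_root=bool(i.get("includeRoot", False)),
                )
                for i in doc.get("include", [])
            ],
        )
    except KeyError as exc:
        raise TerminologyError(f"value-set document missing {exc}") from None


_PACKAGED_SYSTEM_FILES = [
    "codesystem-statistic-type.json",
    "codesystem-certainty-aspect.json",
    "codesystem-certainty-rating.json",
    "codesystem-certainty-modifier.json",
    "codesystem-variable-role.json",
    "codesystem-attribute-estimate-type.json",
    "codesystem-statistical-model.json",
    "codesystem-study-design.json",
    "codesystem-risk-of-bias.json",
]


def load_packaged_terminologies() -> Registry:
    """Build the registry from the data files shipped with the package."""
    registry = Registry()
    data = importlib_resources.files("ebmkit") / "data"
    for name in _PACKAGED_SYSTEM_FILES:
        try:
            doc = json.loads((data / name).read_text(encoding="utf-8"))
        except (FileNotFoundError, json.JSONDecodeError) as exc:
            raise TerminologyError(f"packaged terminology {name} unreadable: {exc}")
        registry.register_system(load_code_system(doc))
    vs_doc = json.loads((data / "valuesets.json").read_text(encoding="utf-8"))
    for entry in vs_doc["valueSets"]:
        registry.register_value_set(load_value_set(entry))
    return registry
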