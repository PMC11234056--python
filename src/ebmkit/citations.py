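"""RIS and MEDLINE (PubMed nbib) to Citation conversion.

Both formats are tagged plain text.  RIS records run from ``TY`` to ``ER``
with ``XX  - value`` lines; MEDLINE records start at ``PMID`` with
``TAG - value`` lines and wrap long values onto continuation lines that
begin with whitespace (joined with a single space on parse).

The tag maps are fixed tables (see ``RIS_TAG_MAP`` / ``MEDLINE_TAG_MAP``).
Conversion is lossless up to those maps: every input tag is either mapped
into the Citation or retained verbatim as a classifier annotation -- never
dropped silently.  Author order in the record is contributor order out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import model as m
from .errors import ConversionError, MalformedDocumentError

__all__ = [
    "TaggedRecord",
    "parse_ris",
    "parse_medline",
    "record_to_citation",
    "RIS_TAG_MAP",
    "MEDLINE_TAG_MAP",
]

#: RIS tags with a structural mapping; everything else is retained.
RIS_TAG_MAP = {
    "TY": "publication type",
    "TI": "title",
    "T1": "title",
    "AU": "author",
    "A1": "author",
    "PY": "year",
    "Y1": "year",
    "JO": "journal",
    "JF": "journal",
    "T2": "journal",
    "VL": "volume",
    "IS": "issue",
    "SP": "first page",
    "EP": "last page",
    "DO": "doi",
    "AN": "accession number",
    "AB": "abstract",
    "UR": "url",
}

#: MEDLINE/nbib tags with a structural mapping.
MEDLINE_TAG_MAP = {
    "PMID": "pmid",
    "TI": "title",
    "AB": "abstract",
    "AU": "author (abbreviated)",
    "FAU": "author (full)",
    "TA": "journal (abbreviation)",
    "JT": "journal (full)",
    "DP": "date of publication",
    "VI": "volume",
    "IP": "issue",
    "PG": "pages",
    "AID": "article identifier",
    "LID": "location identifier",
}

_TAG_SYSTEM = "urn:ebmkit:codesystem:unmapped-tag"


@dataclass
class TaggedRecord:
    """One bibliographic record as an ordered tag/value list."""

    format: str  # "ris" | "medline"
    fields: list[tuple[str, str]] = field(default_factory=list)
    source_line_span: tuple[int, int] = (0, 0)
    warnings: list[str] = field(default_factory=list)

    def values(self, *tags: str) -> list[str]:
        return [v for t, v in self.fields if t in tags]

    def first(self, *tags: str) -> Optional[str]:
        values = self.values(*tags)
        return values[0] if values else None


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])\s{2}-\s?(.*)$")


def parse_ris(text: str, mode: str = "lenient") -> list[TaggedRecord]:
    """Parse RIS text into records (``TY`` ... ``ER`` delimited).

    Tag order and repeats (e.g. multiple ``AU``) are preserved.  A record
    without ``TY`` is skipped with a warning in lenient mode and raises in
    strict mode.
    """
    records: list[TaggedRecord] = []
    current: Optional[TaggedRecord] = None
    start_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        match = _RIS_TAG.match(line)
        if match is None:
            # continuation of the previous value
            if current is not None and current.fields:
                tag, value = current.fields[-1]
                current.fields[-1] = (tag, f"{value} {line.strip()}".strip())
            continue
        tag, value = match.group(1), match.group(2).strip()
        if current is None:
            current = TaggedRecord(format="ris")
            start_line = lineno
        if tag == "ER":
            current.source_line_span = (start_line, lineno)
            records.append(current)
            current = None
            continue
        current.fields.append((tag, value))
    if current is not None and current.fields:
        current.source_line_span = (start_line, lineno)
        current.warnings.append("record not terminated by ER")
        records.append(current)
    kept: list[TaggedRecord] = []
    for rec in records:
        if not rec.values("TY"):
            if mode == "strict":
                raise MalformedDocumentError(
                    f"RIS record at lines {rec.source_line_span} has no TY tag"
                )
            rec.warnings.append("record without TY skipped")
            continue
        kept.append(rec)
    return kept


_MEDLINE_TAG = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s*-\s?(.*)$")


def parse_medline(text: str, mode: str = "lenient") -> list[TaggedRecord]:
    """Parse MEDLINE/nbib text; a ``PMID`` tag starts a new record.

    Continuation lines (leading whitespace) are joined to the previous
    value with a single space.
    """
    records: list[TaggedRecord] = []
    current: Optional[TaggedRecord] = None
    start_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        if raw[0].isspace():
            if current is not None and current.fields:
                tag, value = current.fields[-1]
                current.fields[-1] = (tag, f"{value} {raw.strip()}".strip())
            continue
        match = _MEDLINE_TAG.match(raw)
        if match is None:
            msg = f"line {lineno}: malformed tag line {raw.strip()!r}"
            if mode == "strict":
                raise MalformedDocumentError(msg)
            if current is not None:
                current.warnings.append(msg)
            continue
        tag, value = match.group(1), match.group(2).strip()
        if tag == "PMID" or current is None:
            if current is not None:
                current.source_line_span = (start_line, lineno - 1)
                records.append(current)
            current = TaggedRecord(format="medline")
            start_line = lineno
        current.fields.append((tag, value))
    if current is not None:
        current.source_line_span = (start_line, lineno)
        records.append(current)
    return records


def _retained_classifier(tag: str, value: str, fmt: str) -> m.CodeableConcept:
    return m.CodeableConcept(
        coding=[m.Coding(system=_TAG_SYSTEM, code=f"{fmt}.{tag}")],
        text=f"{tag}: {value}",
    )


def _pages(first: Optional[str], last: Optional[str]) -> tuple:
    return first, last


def _ris_to_citation(r: TaggedRecord, citation_id: str) -> m.CitationResource:
    title = r.first("TI", "T1")
    journal = r.first("JO", "JF", "T2")
    identifiers: list[m.Identifier] = []
    doi = r.first("DO")
    if doi:
        identifiers.append(m.Identifier(type="doi", value=doi))
    accession = r.first("AN")
    if accession:
        identifiers.append(m.Identifier(type="accession", value=accession))
    contributors = [m.Contributor(name=v) for v in r.values("AU", "A1")]
    year = r.first("PY", "Y1")
    if year:
        year = year.split("/")[0].strip()
    classifiers: list[m.CodeableConcept] = []
    pub_type = r.first("TY")
    if pub_type:
        classifiers.append(
            m.CodeableConcept(
                coding=[m.Coding(system=_TAG_SYSTEM, code=f"ris.TY.{pub_type}")],
                text=f"publication type: {pub_type}",
            )
        )
    # chosen journal tag wins; sibling journal tags and unmapped tags retained
    journal_tag_used = next(
        (t for t in ("JO", "JF", "T2") if r.first(t) == journal and journal), None
    )
    for tag, value in r.fields:
        if tag in ("TY", "TI", "T1", "AU", "A1", "PY", "Y1", "VL", "IS", "SP",
                   "EP", "DO", "AN", "AB", "UR"):
            continue
        if tag in ("JO", "JF", "T2") and tag == journal_tag_used:
            continue
        classifiers.append(_retained_classifier(tag, value, "ris"))
    web = r.values("UR")
    return m.CitationResource(
        id=citation_id,
        summary=title,
        cited_artifact=m.CitedArtifact(
            identifiers=identifiers,
            title=title,
            abstract=r.first("AB"),
            publication_form=m.PublicationForm(
                published_in_title=journal,
                date=year,
                volume=r.first("VL"),
                issue=r.first("IS"),
                first_page=r.first("SP"),
                last_page=r.first("EP"),
            ),
            web_locations=web,
            contributorship=contributors,
            classifiers=classifiers,
        ),
    )


def _medline_to_citation(r: TaggedRecord, citation_id: str) -> m.CitationResource:
    title = r.first("TI")
    identifiers: list[m.Identifier] = []
    pmid = r.first("PMID")
    if pmid:
        identifiers.append(m.Identifier(type="pmid", value=pmid))
    doi = None
    for value in r.values("AID", "LID"):
        if value.endswith("[doi]"):
            doi = value[: -len("[doi]")].strip()
            break
    if doi:
        identifiers.append(m.Identifier(type="doi", value=doi))
    full_authors = r.values("FAU")
    contributors = [
        m.Contributor(name=v) for v in (full_authors or r.values("AU"))
    ]
    journal = r.first("TA") or r.first("JT")
    journal_tag_used = "TA" if r.first("TA") else ("JT" if r.first("JT") else None)
    pages = r.first("PG")
    first_page = last_page = None
    if pages:
        parts = pages.split("-", 1)
        first_page = parts[0].strip()
        last_page = parts[1].strip() if len(parts) > 1 else None
    classifiers: list[m.CodeableConcept] = []
    for tag, value in r.fields:
        if tag in ("PMID", "TI", "AB", "DP", "VI", "IP", "PG"):
            continue
        if tag == "FAU":
            continue
        if tag == "AU" and not full_authors:
            continue
        if tag in ("AID", "LID") and doi and value.endswith("[doi]"):
            continue
        if tag == journal_tag_used:
            continue
        classifiers.append(_retained_classifier(tag, value, "medline"))
    date = r.first("DP")
    return m.CitationResource(
        id=citation_id,
        summary=title,
        cited_artifact=m.CitedArtifact(
            identifiers=identifiers,
            title=title,
            abstract=r.first("AB"),
            publication_form=m.PublicationForm(
                published_in_title=journal,
                date=date,
                volume=r.first("VI"),
                issue=r.first("IP"),
                first_page=first_page,
                last_page=last_page,
            ),
            contributorship=contributors,
            classifiers=classifiers,
        ),
    )


_counter = {"n": 0}


def record_to_citation(
    r: TaggedRecord, citation_id: Optional[str] = None
) -> m.CitationResource:
    """Convert one tagged record into a Citation resource.

    Raises :class:`ConversionError` when the record carries neither a
    title nor any identifier.
    """
    if citation_id is None:
        pmid = r.first("PMID") if r.format == "medline" else None
        doi = r.first("DO") if r.format == "ris" else None
        if pmid:
            citation_id = f"pmid-{pmid}"
        elif doi:
            citation_id = "doi-" + re.sub(r"[^A-Za-z0-9]+", "-", doi).strip("-")
        else:
            _counter["n"] += 1
            citation_id = f"citation-{_counter['n']}"
    if r.format == "ris":
        citation = _ris_to_citation(r, citation_id)
    elif r.format == "medline":
        citation = _medline_to_citation(r, citation_id)
    else:
        raise ConversionError(f"unknown record format {r.format!r}")
    ca = citation.cited_artifact
    if not ca.title and not ca.identifiers:
        raise ConversionError(
            "record has neither a title nor an identifier; cannot cite"
        )
    return citation
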