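"""Data model and I/O for longitudinal clinical corpora.

Holds the document/patient containers, the normalised temporal value type
(``NormValue``), the onset-mention annotation schema, and the construction
of the two reference standards used downstream:

* paragraph-level binary labels (a paragraph is positive iff it overlaps a
  past-anchored onset mention that carries a normalised value), and
* adjudicated patient-level reference dates (earliest value per clinical
  type, at most three per patient).

Corpora are stored as JSON-lines (one document per line), annotations as
JSON-lines standoff records keyed by ``doc_id``, and patient metadata as a
CSV with header ``patient_id,first_referral_date,date_of_birth,teams``.
All character offsets are 0-based half-open intervals into the raw
(pre-HTML-stripping) document text.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("onsetnlp")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus, annotation, or metadata records."""


class Granularity(str, Enum):
    YEAR = "YEAR"
    MONTH = "MONTH"
    DAY = "DAY"
    AGE = "AGE"


class TimeInformation(str, Enum):
    PAST_ANCHORED = "PAST_ANCHORED"
    PAST_NOT_ANCHORED = "PAST_NOT_ANCHORED"
    CURRENT = "CURRENT"


class ClinicalType(str, Enum):
    SYMPTOM = "SYMPTOM"
    DIAGNOSIS = "DIAGNOSIS"
    NON_SPECIFIC = "NON_SPECIFIC"


_NORMVALUE_RE = re.compile(
    r"^(?:(?P<year>\d{4})(?:-(?P<month>\d{2})(?:-(?P<day>\d{2}))?)?|AGE(?P<age>\d{1,3})Y)$"
)


@dataclass(frozen=True, order=False)
class NormValue:
    """A normalised temporal value: a calendar date or an age.

    Rendered exactly as ``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD`` or
    ``AGE<n>Y``; :meth:`parse` and :meth:`render` round-trip losslessly.
    """

    kind: str  # "DATE" | "AGE"
    year: Optional[int] = None
    month: Optional[int] = None
    day: Optional[int] = None
    age_years: Optional[int] = None
    granularity: Granularity = Granularity.YEAR

    def __post_init__(self) -> None:
        if self.kind == "DATE":
            if self.year is None or self.age_years is not None:
                raise ValueError("DATE value requires year and no age_years")
            if self.month is not None and not 1 <= self.month <= 12:
                raise ValueError(f"month out of range: {self.month}")
            if self.day is not None and not 1 <= self.day <= 31:
                raise ValueError(f"day out of range: {self.day}")
            if self.granularity not in (Granularity.YEAR, Granularity.MONTH, Granularity.DAY):
                raise ValueError("DATE granularity must be YEAR/MONTH/DAY")
        elif self.kind == "AGE":
            if self.age_years is None or self.age_years < 0:
                raise ValueError("AGE value requires non-negative age_years")
            if self.year is not None or self.month is not None or self.day is not None:
                raise ValueError("AGE value must not carry calendar fields")
            if self.granularity is not Granularity.AGE:
                raise ValueError("AGE values have AGE granularity")
        else:
            raise ValueError(f"unknown kind: {self.kind!r}")

    @staticmethod
    def date(year: int, month: Optional[int] = None, day: Optional[int] = None) -> "NormValue":
        if day is not None:
            gran = Granularity.DAY
        elif month is not None:
            gran = Granularity.MONTH
        else:
            gran = Granularity.YEAR
        return NormValue(kind="DATE", year=year, month=month, day=day, granularity=gran)

    @staticmethod
    def age(age_years: int) -> "NormValue":
        return NormValue(kind="AGE", age_years=age_years, granularity=Granularity.AGE)

    @staticmethod
    def parse(text: str) -> "NormValue":
        m = _NORMVALUE_RE.match(text.strip())
        if not m:
            raise ValueError(f"unparseable normalised value: {text!r}")
        if m.group("age") is not None:
            return NormValue.age(int(m.group("age")))
        month = int(m.group("month")) if m.group("month") else None
        day = int(m.group("day")) if m.group("day") else None
        return NormValue.date(int(m.group("year")), month, day)

    def render(self) -> str:
        if self.kind == "AGE":
            return f"AGE{self.age_years}Y"
        if self.granularity is Granularity.DAY:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.granularity is Granularity.MONTH:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def to_year(self) -> "NormValue":
        """Reduce a DATE to year granularity; AGE values pass through."""
        if self.kind == "AGE":
            return self
        return NormValue.date(self.year)

    def sort_key(self) -> tuple:
        """Total order: dates (by calendar position) before ages (by age)."""
        if self.kind == "DATE":
            return (0, self.year, self.month or 0, self.day or 0)
        return (1, self.age_years, 0, 0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class Document:
    doc_id: str
    patient_id: str
    document_date: date
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id or not self.patient_id:
            raise ValueError("doc_id and patient_id must be non-empty")
        if not self.text:
            raise ValueError(f"document {self.doc_id}: empty text")
        if not isinstance(self.document_date, date):
            raise ValueError(f"document {self.doc_id}: document_date must be a date")


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    first_referral_date: date
    date_of_birth: Optional[date] = None
    team_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.date_of_birth is not None and self.first_referral_date < self.date_of_birth:
            raise ValueError(
                f"patient {self.patient_id}: first referral precedes date of birth"
            )


@dataclass(frozen=True)
class OnsetMention:
    """An annotated onset mention (standoff) with the three-attribute schema.

    ``value`` is only defined for past-anchored mentions; the constructor
    enforces this.
    """

    doc_id: str
    span: tuple  # (start, end), 0-based half-open into raw document text
    time_information: TimeInformation
    value: Optional[NormValue] = None
    clinical_type: ClinicalType = ClinicalType.NON_SPECIFIC
    annotator_id: str = "gold"

    def __post_init__(self) -> None:
        start, end = self.span
        if not (0 <= start < end):
            raise ValueError(f"invalid span {self.span}")
        if self.value is not None and self.time_information is not TimeInformation.PAST_ANCHORED:
            raise ValueError(
                "a normalised value is only defined for past-anchored mentions"
            )


@dataclass
class PatientReference:
    """Adjudicated patient-level reference: earliest value per clinical type.

    When a clinical type has both date-valued and age-valued mentions the
    type slot keeps the date (directly usable for treatment-delay
    computation) and the earliest age is retained in ``secondary_ages``.
    """

    patient_id: str
    values: dict = field(default_factory=dict)  # ClinicalType -> NormValue
    secondary_ages: dict = field(default_factory=dict)  # ClinicalType -> NormValue

    @property
    def reference_values(self) -> set:
        return set(self.values.values())

    def all_values(self) -> set:
        return set(self.values.values()) | set(self.secondary_ages.values())

    def is_empty(self) -> bool:
        return not self.values


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_date(raw: str, where: str) -> date:
    try:
        return date.fromisoformat(str(raw))
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: unparseable date {raw!r}") from exc


def read_corpus(path, format: str = "jsonl") -> list:
    """Read a JSON-lines corpus into validated :class:`Document` objects."""
    if format != "jsonl":
        raise ValueError(f"unsupported corpus format: {format!r}")
    documents = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON") from exc
            for key in ("doc_id", "patient_id", "document_date", "text"):
                if key not in rec or rec[key] in (None, ""):
                    raise CorpusFormatError(f"line {lineno}: missing field {key!r}")
            if rec["doc_id"] in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate doc_id {rec['doc_id']!r}")
            seen.add(rec["doc_id"])
            documents.append(
                Document(
                    doc_id=str(rec["doc_id"]),
                    patient_id=str(rec["patient_id"]),
                    document_date=_parse_date(rec["document_date"], f"line {lineno}"),
                    text=rec["text"],
                )
            )
    logger.info("read %d documents from %s", len(documents), path)
    return documents


def write_corpus(path, documents: Iterable[Document]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "patient_id": doc.patient_id,
                        "document_date": doc.document_date.isoformat(),
                        "text": doc.text,
                    }
                )
                + "\n"
            )


def read_annotations(path, documents: Optional[Sequence[Document]] = None) -> list:
    """Read standoff onset-mention annotations (JSON-lines).

    If ``documents`` is given, mentions must reference known doc_ids and
    spans must lie within the document text.
    """
    by_id = {d.doc_id: d for d in documents} if documents is not None else None
    mentions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON") from exc
            try:
                mention = OnsetMention(
                    doc_id=str(rec["doc_id"]),
                    span=(int(rec["start"]), int(rec["end"])),
                    time_information=TimeInformation(rec["time_information"]),
                    value=NormValue.parse(rec["value"]) if rec.get("value") else None,
                    clinical_type=ClinicalType(rec["clinical_type"]),
                    annotator_id=str(rec.get("annotator_id", "gold")),
                )
            except (KeyError, ValueError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
            if by_id is not None:
                if mention.doc_id not in by_id:
                    raise CorpusFormatError(
                        f"line {lineno}: unknown doc_id {mention.doc_id!r}"
                    )
                if mention.span[1] > len(by_id[mention.doc_id].text):
                    raise CorpusFormatError(
                        f"line {lineno}: span {mention.span} out of bounds"
                    )
            mentions.append(mention)
    logger.info("read %d onset mentions from %s", len(mentions), path)
    return mentions


def write_annotations(path, mentions: Iterable[OnsetMention]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "doc_id": m.doc_id,
                        "start": m.span[0],
                        "end": m.span[1],
                        "time_information": m.time_information.value,
                        "value": m.value.render() if m.value else None,
                        "clinical_type": m.clinical_type.value,
                        "annotator_id": m.annotator_id,
                    }
                )
                + "\n"
            )


def read_patient_meta(path) -> list:
    """Read patient metadata CSV (patient_id, first_referral_date, date_of_birth, teams)."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    metas = []
    for i, row in frame.iterrows():
        if not row.get("patient_id"):
            raise CorpusFormatError(f"metadata row {i}: missing patient_id")
        dob = row.get("date_of_birth") or None
        teams = frozenset(t for t in str(row.get("teams", "")).split(";") if t)
        metas.append(
            PatientMeta(
                patient_id=row["patient_id"],
                first_referral_date=_parse_date(row["first_referral_date"], f"row {i}"),
                date_of_birth=_parse_date(dob, f"row {i}") if dob else None,
                team_labels=teams,
            )
        )
    return metas


def write_patient_meta(path, metas: Iterable[PatientMeta]) -> None:
    rows = [
        {
            "patient_id": m.patient_id,
            "first_referral_date": m.first_referral_date.isoformat(),
            "date_of_birth": m.date_of_birth.isoformat() if m.date_of_birth else "",
            "teams": ";".join(sorted(m.team_labels)),
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reference-standard construction
# ---------------------------------------------------------------------------

def _overlaps(a: tuple, b: tuple) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def build_paragraph_labels(mentions: Iterable[OnsetMention], paragraphs: Sequence) -> list:
    """Assign binary labels to paragraphs from onset-mention annotations.

    A paragraph is labelled 1 iff it overlaps a past-anchored mention that
    carries a normalised value; all other paragraphs are labelled 0.  A
    mention straddling a paragraph boundary labels every paragraph it
    touches.  Mentions referencing a document with no paragraphs are
    dropped with a warning.  Labels are set in place and the paragraph
    list is returned.
    """
    by_doc: dict = {}
    for p in paragraphs:
        p.label = 0
        by_doc.setdefault(p.doc_id, []).append(p)
    for m in mentions:
        if m.time_information is not TimeInformation.PAST_ANCHORED or m.value is None:
            continue
        if m.doc_id not in by_doc:
            logger.warning(
                "mention %s in document %s with no paragraphs; dropped", m.span, m.doc_id
            )
            continue
        for p in by_doc[m.doc_id]:
            if _overlaps(m.span, p.span):
                p.label = 1
    return list(paragraphs)


def adjudicate_patient(patient_id: str, mentions: Iterable[OnsetMention]) -> PatientReference:
    """Adjudicate one patient's mentions into per-type earliest reference values.

    For each clinical type with at least one past-anchored valued mention,
    the earliest value is selected (year-granularity comparison; ages are
    compared among ages).  If a type carries both dates and ages, the slot
    keeps the earliest date and the earliest age goes to ``secondary_ages``.
    The result is invariant to mention order.
    """
    ref = PatientReference(patient_id=patient_id)
    by_type: dict = {}
    for m in mentions:
        if m.time_information is TimeInformation.PAST_ANCHORED and m.value is not None:
            by_type.setdefault(m.clinical_type, []).append(m.value)
    for ctype, values in by_type.items():
        dates = sorted((v.to_year() for v in values if v.kind == "DATE"),
                       key=NormValue.sort_key)
        ages = sorted((v for v in values if v.kind == "AGE"), key=NormValue.sort_key)
        if dates:
            ref.values[ctype] = dates[0]
            if ages:
                ref.secondary_ages[ctype] = ages[0]
        elif ages:
            ref.values[ctype] = ages[0]
    return ref


def adjudicate_all(mentions: Iterable[OnsetMention],
                   patient_of_doc: Mapping[str, str]) -> dict:
    """Group mentions by patient via a doc->patient map and adjudicate each."""
    per_patient: dict = {}
    for m in mentions:
        pid = patient_of_doc[m.doc_id]
        per_patient.setdefault(pid, []).append(m)
    return {pid: adjudicate_patient(pid, ms) for pid, ms in per_patient.items()}
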