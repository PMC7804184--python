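"""Patient-level aggregation of classified paragraphs into ranked onset dates.

From each positively classified paragraph the earliest date and earliest
age (year granularity) become candidate onset values carrying the
paragraph's classifier probability.  Per patient, candidates are
de-duplicated (highest probability wins), ranked by probability, cleaned
with rule-based plausibility filters (pre-1900 dates, Mental Health Act
1983 artefacts, the patient's current age, sentences about relatives,
dates after the first referral) and truncated to the top three.  The
duration of untreated psychosis (DUP) is the referral year minus the
onset year, with -1 reported as 0 (one-year error margin).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

from . import temporal
from .corpus import NormValue, PatientMeta
from .segment import Paragraph

logger = logging.getLogger("onsetnlp")

DEFAULT_RELATIVE_LEXICON = (
    "mother", "father", "brother", "sister", "son", "daughter", "aunt",
    "uncle", "grandmother", "grandfather", "wife", "husband", "partner",
)

_SENTENCE_BREAK = re.compile(r"[.!?\n]")


@dataclass(frozen=True)
class CandidateDate:
    patient_id: str
    value: NormValue  # year or age granularity
    probability: float
    source: tuple  # (doc_id, paragraph_index)
    document_date: object  # datetime.date
    source_sentence: str = ""

    def __post_init__(self) -> None:
        if self.value.granularity not in ("YEAR", "AGE"):
            raise ValueError("candidate values must be year- or age-granular")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


@dataclass
class PatientPrediction:
    patient_id: str
    candidates: List[CandidateDate] = field(default_factory=list)


@dataclass(frozen=True)
class CleanConfig:
    min_year: int = 1900
    mha_year: int = 1983
    mha_pattern: str = r"mental\s+health\s+act"
    relative_lexicon: tuple = DEFAULT_RELATIVE_LEXICON
    max_candidates: int = 3


def _sentence_around(text: str, span: tuple) -> str:
    """The sentence of ``text`` containing the character interval ``span``."""
    start = 0
    for m in _SENTENCE_BREAK.finditer(text, 0, span[0]):
        start = m.end()
    m = _SENTENCE_BREAK.search(text, span[1])
    end = m.end() if m else len(text)
    return text[start:end].strip()


def extract_candidates(
    paragraph: Paragraph,
    probability: float,
    patient_id: str,
    document_date,
) -> List[CandidateDate]:
    """At most one date and one age candidate from a classified paragraph."""
    candidates: List[CandidateDate] = []
    date_exprs = [e for e in paragraph.expressions
                  if e.value is not None and e.value.kind == "DATE"]
    age_exprs = [e for e in paragraph.expressions
                 if e.value is not None and e.value.kind == "AGE"]
    if date_exprs:
        best = min(date_exprs, key=lambda e: e.value.sort_key())
        candidates.append(
            CandidateDate(
                patient_id=patient_id,
                value=best.value.to_year(),
                probability=probability,
                source=(paragraph.doc_id, paragraph.index),
                document_date=document_date,
                source_sentence=_sentence_around(paragraph.text, best.span),
            )
        )
    if age_exprs:
        best = min(age_exprs, key=lambda e: e.value.sort_key())
        candidates.append(
            CandidateDate(
                patient_id=patient_id,
                value=best.value,
                probability=probability,
                source=(paragraph.doc_id, paragraph.index),
                document_date=document_date,
                source_sentence=_sentence_around(paragraph.text, best.span),
            )
        )
    return candidates


def rank_patient(candidates: Iterable[CandidateDate]) -> PatientPrediction:
    """Merge duplicate values (max probability) and rank by probability.

    Ties break on earlier document date, then earlier value; the result is
    deterministic and invariant to input order.
    """
    candidates = list(candidates)
    if not candidates:
        return PatientPrediction(patient_id="", candidates=[])
    pid = candidates[0].patient_id
    best: dict = {}
    for c in candidates:
        key = c.value.render()
        incumbent = best.get(key)
        if incumbent is None or _dedup_key(c) < _dedup_key(incumbent):
            best[key] = c
    ranked = sorted(
        best.values(),
        key=lambda c: (-c.probability, _date_ord(c), c.value.sort_key()),
    )
    return PatientPrediction(patient_id=pid, candidates=ranked)


def _date_ord(c: CandidateDate) -> int:
    return c.document_date.toordinal()


def _dedup_key(c: CandidateDate) -> tuple:
    # prefer higher probability, then earlier document, then smaller source id
    return (-c.probability, _date_ord(c), c.source)


def clean_candidates(
    prediction: PatientPrediction,
    meta: PatientMeta,
    relative_flags: Optional[Sequence[bool]] = None,
    config: CleanConfig = CleanConfig(),
) -> PatientPrediction:
    """Apply large-scale cleaning rules and truncate to the top three.

    Removes date candidates before 1900; 1983 dates whose source sentence
    matches the Mental Health Act pattern; age candidates equal to the
    patient's age at referral (skipped with a warning without a date of
    birth); candidates whose source sentence mentions a relative; and
    dates after the first referral year.
    """
    referral_year = meta.first_referral_date.year
    age_at_referral = None
    if meta.date_of_birth is not None:
        dob = meta.date_of_birth
        ref = meta.first_referral_date
        age_at_referral = ref.year - dob.year - ((ref.month, ref.day) < (dob.month, dob.day))
    mha = re.compile(config.mha_pattern, re.IGNORECASE)
    relative = re.compile(
        r"\b(?:" + "|".join(config.relative_lexicon) + r")\b", re.IGNORECASE
    )
    kept: List[CandidateDate] = []
    warned_dob = False
    for i, c in enumerate(prediction.candidates):
        if c.value.kind == "DATE":
            if c.value.year < config.min_year:
                continue
            if c.value.year == config.mha_year and mha.search(c.source_sentence):
                continue
            if c.value.year > referral_year:
                continue
        else:
            if age_at_referral is None:
                if not warned_dob:
                    logger.warning(
                        "patient %s: no date of birth; current-age rule skipped",
                        prediction.patient_id,
                    )
                    warned_dob = True
            elif c.value.age_years == age_at_referral:
                continue
        flagged = (
            relative_flags[i]
            if relative_flags is not None
            else bool(relative.search(c.source_sentence))
        )
        if flagged:
            continue
        kept.append(c)
    return PatientPrediction(
        patient_id=prediction.patient_id, candidates=kept[: config.max_candidates]
    )


def compute_dup(value: NormValue, meta: PatientMeta) -> int:
    """DUP in whole years: referral year minus onset year; -1 reports as 0."""
    if value.kind == "AGE":
        if meta.date_of_birth is None:
            raise ValueError(
                f"patient {meta.patient_id}: age-valued onset needs a date of birth"
            )
        onset_year = meta.date_of_birth.year + value.age_years
    else:
        onset_year = value.year
    dup = meta.first_referral_date.year - onset_year
    if dup == -1:
        return 0
    if dup < -1:
        raise ValueError(f"onset year {onset_year} after referral year by more than 1")
    return dup


def baseline_earliest(candidates: Iterable[CandidateDate], n: int = 3) -> List[NormValue]:
    """Baseline: the ``n`` chronologically earliest distinct date values.

    Ignores classifier probability entirely (ranking-free comparator).
    """
    years = sorted({c.value.year for c in candidates if c.value.kind == "DATE"})
    return [NormValue.date(y) for y in years[:n]]
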