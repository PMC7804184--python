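"""Evaluation metrics and inter-annotator agreement.

Paragraph-level precision/recall/F1, patient-level top-N match and
precision/recall@N against adjudicated reference dates, the relative
match (predicted vs gold-paragraph aggregation), F1-style agreement at
paragraph / attribute / patient level, and grouped DUP summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import PatientPrediction
from .corpus import (
    NormValue,
    OnsetMention,
    PatientReference,
    TimeInformation,
)

logger = logging.getLogger("onsetnlp")


@dataclass(frozen=True)
class TopNReport:
    n: int
    matched_patients: int
    total_patients: int
    match_rate: float
    mean_precision_at_n: float
    mean_recall_at_n: float


@dataclass
class AgreementReport:
    paragraph_f1: float
    attribute_agreement: dict = field(default_factory=dict)
    patient_level_agreement: float = 0.0


# ---------------------------------------------------------------------------
# Paragraph-level classification metrics
# ---------------------------------------------------------------------------

def paragraph_prf(predicted: Sequence[int], reference: Sequence[int]) -> tuple:
    """Precision, recall and F1 on the positive class.

    Degenerate cases follow the zero-division-to-zero convention.
    """
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference label sequences differ in length")
    tp = int(np.sum((pred == 1) & (ref == 1)))
    fp = int(np.sum((pred == 1) & (ref == 0)))
    fn = int(np.sum((pred == 0) & (ref == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Patient-level top-N evaluation
# ---------------------------------------------------------------------------

def _values_match(a: NormValue, b: NormValue, birth_year: Optional[int]) -> bool:
    """Same year or same age; date<->age cross-match via birth year if known."""
    if a.kind == b.kind:
        if a.kind == "DATE":
            return a.year == b.year
        return a.age_years == b.age_years
    if birth_year is None:
        return False
    date_v, age_v = (a, b) if a.kind == "DATE" else (b, a)
    return date_v.year == birth_year + age_v.age_years


def topn_match(
    prediction: PatientPrediction,
    reference: PatientReference,
    n: int,
    birth_year: Optional[int] = None,
) -> bool:
    """True iff any top-n candidate value equals a reference onset value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    refs = reference.all_values()
    return any(
        _values_match(c.value, r, birth_year)
        for c in prediction.candidates[:n]
        for r in refs
    )


def precision_recall_at_n(
    predictions: Mapping[str, PatientPrediction],
    references: Mapping[str, PatientReference],
    n: int,
    birth_years: Optional[Mapping[str, int]] = None,
    denominator: str = "min",
) -> tuple:
    """Mean precision@n and recall@n over patients with a non-empty reference.

    precision@n divides by ``min(n, |top-n|)`` by default, so short
    candidate lists are not penalised for their length; pass
    ``denominator="n"`` for the plain convention.  recall@n divides by the
    number of reference values.
    """
    precisions, recalls = [], []
    for pid, ref in references.items():
        if ref.is_empty():
            continue
        by = (birth_years or {}).get(pid)
        pred = predictions.get(pid, PatientPrediction(patient_id=pid))
        top = pred.candidates[:n]
        ref_vals = ref.all_values()
        hit_candidates = sum(
            any(_values_match(c.value, r, by) for r in ref_vals) for c in top
        )
        hit_refs = sum(
            any(_values_match(c.value, r, by) for c in top) for r in ref.reference_values
        )
        denom = min(n, len(top)) if denominator == "min" else n
        precisions.append(hit_candidates / denom if denom else 0.0)
        recalls.append(hit_refs / len(ref.reference_values))
    if not precisions:
        return 0.0, 0.0
    return float(np.mean(precisions)), float(np.mean(recalls))


def topn_report(
    predictions: Mapping[str, PatientPrediction],
    references: Mapping[str, PatientReference],
    n: int,
    birth_years: Optional[Mapping[str, int]] = None,
) -> TopNReport:
    """Top-N match over patients with a non-empty (past-anchored) reference."""
    eligible = [pid for pid, ref in references.items() if not ref.is_empty()]
    matched = sum(
        topn_match(
            predictions.get(pid, PatientPrediction(patient_id=pid)),
            references[pid],
            n,
            (birth_years or {}).get(pid),
        )
        for pid in eligible
    )
    prec, rec = precision_recall_at_n(predictions, references, n, birth_years)
    total = len(eligible)
    return TopNReport(
        n=n,
        matched_patients=int(matched),
        total_patients=total,
        match_rate=matched / total if total else 0.0,
        mean_precision_at_n=prec,
        mean_recall_at_n=rec,
    )


def relative_match(prediction_match_count: int, reference_match_count: int) -> float:
    """Predicted-paragraph matches divided by gold-paragraph matches."""
    if reference_match_count <= 0:
        raise ValueError("reference match count must be positive")
    return prediction_match_count / reference_match_count


# ---------------------------------------------------------------------------
# Inter-annotator agreement
# ---------------------------------------------------------------------------

def _overlaps(a: tuple, b: tuple) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _project_to_paragraphs(mentions: Iterable[OnsetMention], paragraphs) -> set:
    known_docs = {p.doc_id for p in paragraphs}
    marked = set()
    for m in mentions:
        if m.doc_id not in known_docs:
            raise ValueError(f"mention references unknown document {m.doc_id!r}")
        for p in paragraphs:
            if p.doc_id == m.doc_id and _overlaps(m.span, p.span):
                marked.add((p.doc_id, p.index))
    return marked


def iaa_paragraph(annotations_a, annotations_b, paragraphs) -> float:
    """Paragraph-level agreement F1: true positives are paragraphs marked by both."""
    sa = _project_to_paragraphs(annotations_a, paragraphs)
    sb = _project_to_paragraphs(annotations_b, paragraphs)
    tp = len(sa & sb)
    denom = 2 * tp + len(sa - sb) + len(sb - sa)
    return 2 * tp / denom if denom else 1.0


def _overlapping_pairs(annotations_a, annotations_b):
    for a in annotations_a:
        for b in annotations_b:
            if a.doc_id == b.doc_id and _overlaps(a.span, b.span):
                yield a, b


def iaa_attribute(annotations_a, annotations_b, attribute: str) -> Dict[str, float]:
    """Per-value agreement on overlapping mentions.

    For each attribute value, the fraction of overlapping mention pairs
    where both annotators assigned it, among pairs where either did.
    ``attribute`` is ``"time_information"`` or ``"clinical_type"``.
    """
    either: Dict[str, int] = {}
    both: Dict[str, int] = {}
    for a, b in _overlapping_pairs(annotations_a, annotations_b):
        va = getattr(a, attribute).value
        vb = getattr(b, attribute).value
        for v in {va, vb}:
            either[v] = either.get(v, 0) + 1
            if va == vb == v:
                both[v] = both.get(v, 0) + 1
    return {v: both.get(v, 0) / n for v, n in either.items()}


_TIME_PRECEDENCE = [
    TimeInformation.PAST_ANCHORED,
    TimeInformation.PAST_NOT_ANCHORED,
    TimeInformation.CURRENT,
]


def patient_time_label(mentions: Iterable[OnsetMention]) -> Optional[TimeInformation]:
    """Patient-level time-information label by precedence.

    Past anchored beats past not anchored beats current; no mentions
    yields None.
    """
    present = {m.time_information for m in mentions}
    for label in _TIME_PRECEDENCE:
        if label in present:
            return label
    return None


def patient_level_agreement(
    mentions_a_by_patient: Mapping[str, Sequence[OnsetMention]],
    mentions_b_by_patient: Mapping[str, Sequence[OnsetMention]],
) -> float:
    """Fraction of patients whose derived patient-level labels coincide."""
    patients = set(mentions_a_by_patient) | set(mentions_b_by_patient)
    if not patients:
        return 1.0
    agree = sum(
        patient_time_label(mentions_a_by_patient.get(pid, ()))
        == patient_time_label(mentions_b_by_patient.get(pid, ()))
        for pid in patients
    )
    return agree / len(patients)


# ---------------------------------------------------------------------------
# DUP summaries
# ---------------------------------------------------------------------------

def summarize_dup(
    dup_values: Mapping[str, Sequence[int]],
    group_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Group-wise summary of per-patient minimum and maximum DUP.

    For each patient the minimum and maximum of their DUP values are
    taken; per group the patient count, mean, standard deviation
    (population, ddof=0) and range of each are reported.
    """
    rows = []
    for pid, values in dup_values.items():
        if not len(values):
            raise ValueError(f"patient {pid} has no DUP values")
        rows.append(
            {
                "patient_id": pid,
                "group": group_labels[pid],
                "dup_min": min(values),
                "dup_max": max(values),
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for group, sub in frame.groupby("group"):
        out.append(
            {
                "group": group,
                "patients": len(sub),
                "dup_min_mean": float(sub.dup_min.mean()),
                "dup_min_std": float(sub.dup_min.std(ddof=0)),
                "dup_min_low": int(sub.dup_min.min()),
                "dup_min_high": int(sub.dup_min.max()),
                "dup_max_mean": float(sub.dup_max.mean()),
                "dup_max_std": float(sub.dup_max.std(ddof=0)),
                "dup_max_low": int(sub.dup_max.min()),
                "dup_max_high": int(sub.dup_max.max()),
            }
        )
    return pd.DataFrame(out)
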