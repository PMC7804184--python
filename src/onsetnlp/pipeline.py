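"""End-to-end orchestration: corpus -> paragraphs -> classifier -> ranked dates.

Glues the pipeline stages together for experiments and the command line:
segment and tag documents, build labels from annotations, train the
paragraph classifier on a patient-level split, aggregate positive
paragraphs into cleaned ranked candidate lists, and evaluate top-N match
against the adjudicated reference (including the earliest-dates baseline
and the relative match against gold-paragraph aggregation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import aggregate, classify, evaluate, segment, temporal
from .corpus import Document, OnsetMention, PatientMeta, build_paragraph_labels
from .segment import FilterConfig, Paragraph

logger = logging.getLogger("onsetnlp")


def prepare_paragraphs(
    documents: Sequence[Document],
    filter_config: FilterConfig = FilterConfig(),
    tagger_config: temporal.TaggerConfig = temporal.DEFAULT_CONFIG,
) -> List[Paragraph]:
    """Segment documents, tag expressions, and apply the paragraph filters."""
    retained: List[Paragraph] = []
    for doc in documents:
        paragraphs = segment.split_paragraphs(doc)
        segment.attach_expressions(paragraphs, doc.document_date, tagger_config)
        retained.extend(segment.filter_paragraphs(paragraphs, filter_config))
    return retained


def split_patients(patient_ids: Sequence[str], n_test: int, seed: int) -> Tuple[set, set]:
    """Deterministic patient-level train/test split."""
    unique = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    test = set(rng.choice(unique, size=n_test, replace=False))
    return set(unique) - test, test


def aggregate_patients(
    paragraphs: Sequence[Paragraph],
    probabilities: Sequence[float],
    documents_by_id: Mapping[str, Document],
    metas: Mapping[str, PatientMeta],
    threshold: float = 0.5,
    clean: bool = True,
    clean_config: aggregate.CleanConfig = aggregate.CleanConfig(),
) -> Dict[str, aggregate.PatientPrediction]:
    """Rank candidate onset dates per patient from classified paragraphs.

    With ``threshold=None`` every paragraph is ranked by probability
    (keep-all mode); otherwise only paragraphs at or above the operating
    threshold contribute candidates.
    """
    per_patient: Dict[str, list] = {}
    for p, prob in zip(paragraphs, probabilities):
        if threshold is not None and prob < threshold:
            continue
        doc = documents_by_id[p.doc_id]
        for cand in aggregate.extract_candidates(p, float(prob), doc.patient_id, doc.document_date):
            per_patient.setdefault(doc.patient_id, []).append(cand)
    predictions = {}
    for pid, cands in per_patient.items():
        pred = aggregate.rank_patient(cands)
        if clean:
            pred = aggregate.clean_candidates(pred, metas[pid], config=clean_config)
        predictions[pid] = pred
    return predictions


def baseline_predictions(
    paragraphs: Sequence[Paragraph],
    probabilities: Sequence[float],
    documents_by_id: Mapping[str, Document],
    metas: Mapping[str, PatientMeta],
    threshold: float = 0.5,
    clean: bool = True,
    clean_config: aggregate.CleanConfig = aggregate.CleanConfig(),
) -> Dict[str, aggregate.PatientPrediction]:
    """Earliest-dates baseline in :class:`PatientPrediction` form.

    Takes the three chronologically earliest distinct dates among positive
    paragraphs (after the same cleaning rules), ignoring probability.
    """
    per_patient: Dict[str, list] = {}
    for p, prob in zip(paragraphs, probabilities):
        if prob < threshold:
            continue
        doc = documents_by_id[p.doc_id]
        for cand in aggregate.extract_candidates(p, float(prob), doc.patient_id, doc.document_date):
            per_patient.setdefault(doc.patient_id, []).append(cand)
    predictions = {}
    for pid, cands in per_patient.items():
        if clean:
            # apply cleaning rules candidate-wise before the earliest-3 pick
            ranked = aggregate.rank_patient(cands)
            cleaned = aggregate.clean_candidates(
                ranked,
                metas[pid],
                config=aggregate.CleanConfig(
                    min_year=clean_config.min_year,
                    mha_year=clean_config.mha_year,
                    mha_pattern=clean_config.mha_pattern,
                    relative_lexicon=clean_config.relative_lexicon,
                    max_candidates=10**9,
                ),
            )
            cands = cleaned.candidates
        values = aggregate.baseline_earliest(cands, n=3)
        predictions[pid] = aggregate.PatientPrediction(
            patient_id=pid,
            candidates=[
                aggregate.CandidateDate(
                    patient_id=pid,
                    value=v,
                    probability=1.0,
                    source=("baseline", i),
                    document_date=metas[pid].first_referral_date,
                )
                for i, v in enumerate(values)
            ],
        )
    return predictions


@dataclass
class ExperimentResult:
    cv: classify.CVResult
    test_prf: tuple  # paragraph-level (P, R, F1) on the test split
    topn: dict  # n -> TopNReport (predicted paragraphs)
    topn_reference: dict  # n -> TopNReport (gold paragraphs)
    relative: dict  # n -> relative match
    baseline_top3: "evaluate.TopNReport"
    n_train_paragraphs: int = 0
    n_test_paragraphs: int = 0
    extras: dict = field(default_factory=dict)


def run_experiment(
    documents: Sequence[Document],
    annotations: Sequence[OnsetMention],
    metas: Sequence[PatientMeta],
    references: Mapping[str, "object"],
    n_test_patients: int,
    seed: int,
    spec: classify.FeatureSpec = classify.FeatureSpec(),
    config: Optional[classify.TrainConfig] = None,
    ns: Sequence[int] = (1, 3, 5),
    run_cv: bool = True,
) -> ExperimentResult:
    """Train, evaluate and aggregate on a patient-level split.

    Mirrors the reference protocol: patient-grouped 5-fold CV on the
    training split for paragraph metrics, a single model trained on the
    full training split for test-set paragraph metrics, probability-ranked
    candidate aggregation with cleaning, and top-N match evaluated over
    patients holding a past-anchored reference, against both predicted and
    gold paragraphs (relative match), plus the earliest-dates baseline.
    """
    config = config or classify.TrainConfig(seed=seed)
    meta_by_pid = {m.patient_id: m for m in metas}
    docs_by_id = {d.doc_id: d for d in documents}

    paragraphs = prepare_paragraphs(documents)
    build_paragraph_labels(annotations, paragraphs)
    labels = np.array([p.label for p in paragraphs])
    pids = np.array([docs_by_id[p.doc_id].patient_id for p in paragraphs])

    train_pids, test_pids = split_patients(
        [m.patient_id for m in metas], n_test_patients, seed
    )
    tr = np.flatnonzero(np.isin(pids, sorted(train_pids)))
    te = np.flatnonzero(np.isin(pids, sorted(test_pids)))
    tr_paragraphs = [paragraphs[i] for i in tr]
    te_paragraphs = [paragraphs[i] for i in te]

    cv = None
    if run_cv:
        cv = classify.cross_validate(
            tr_paragraphs, labels[tr], pids[tr], spec, config
        )

    X_tr, featurizer = classify.featurize(tr_paragraphs, spec)
    model = classify.train(X_tr, labels[tr], config)
    proba_te = classify.predict_proba(model, featurizer.transform(te_paragraphs))
    test_prf = evaluate.paragraph_prf((proba_te >= 0.5).astype(int), labels[te])

    birth_years = {
        m.patient_id: m.date_of_birth.year for m in metas if m.date_of_birth is not None
    }
    test_refs = {
        pid: ref for pid, ref in references.items() if pid in test_pids
    }

    predictions = aggregate_patients(te_paragraphs, proba_te, docs_by_id, meta_by_pid)
    gold_predictions = aggregate_patients(
        te_paragraphs, labels[te].astype(float), docs_by_id, meta_by_pid
    )
    baseline = baseline_predictions(te_paragraphs, proba_te, docs_by_id, meta_by_pid)

    topn, topn_ref, relative = {}, {}, {}
    for n in ns:
        topn[n] = evaluate.topn_report(predictions, test_refs, n, birth_years)
        topn_ref[n] = evaluate.topn_report(gold_predictions, test_refs, n, birth_years)
        if topn_ref[n].matched_patients:
            relative[n] = evaluate.relative_match(
                topn[n].matched_patients, topn_ref[n].matched_patients
            )
    baseline_top3 = evaluate.topn_report(baseline, test_refs, 3, birth_years)

    return ExperimentResult(
        cv=cv,
        test_prf=test_prf,
        topn=topn,
        topn_reference=topn_ref,
        relative=relative,
        baseline_top3=baseline_top3,
        n_train_paragraphs=len(tr),
        n_test_paragraphs=len(te),
        extras={
            "predictions": predictions,
            "test_patients": test_pids,
            "train_patients": train_pids,
        },
    )


def compute_patient_dups(
    predictions: Mapping[str, aggregate.PatientPrediction],
    metas: Mapping[str, PatientMeta],
) -> Dict[str, List[int]]:
    """Per-patient DUP values (years) from cleaned candidate lists."""
    dups: Dict[str, List[int]] = {}
    for pid, pred in predictions.items():
        values = []
        for c in pred.candidates:
            try:
                values.append(aggregate.compute_dup(c.value, metas[pid]))
            except ValueError:
                logger.warning("patient %s: skipping DUP for %s", pid, c.value.render())
        if values:
            dups[pid] = values
    return dups
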