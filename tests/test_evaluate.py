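"""Metrics: P/R/F1, top-N match, @N scores, agreement, DUP summaries."""

from datetime import date
from itertools import chain, combinations

import numpy as np
import pytest

from onsetnlp import evaluate
from onsetnlp.aggregate import CandidateDate, PatientPrediction
from onsetnlp.corpus import (
    ClinicalType,
    NormValue,
    OnsetMention,
    PatientReference,
    TimeInformation,
)
from onsetnlp.segment import Paragraph


def pred(pid, values, probs=None):
    probs = probs or [0.9 - 0.1 * i for i in range(len(values))]
    return PatientPrediction(
        pid,
        [
            CandidateDate(pid, v, p, ("d", i), date(2015, 1, 1))
            for i, (v, p) in enumerate(zip(values, probs))
        ],
    )


def ref(pid, values):
    return PatientReference(
        patient_id=pid,
        values={t: v for t, v in zip(ClinicalType, values)},
    )


def test_prf_matches_hand_computed_fixture():
    # TP=4 FP=2 FN=3 TN=11 -> P=4/6, R=4/7
    reference = [1, 1, 1, 1, 1, 1, 1] + [0] * 13
    predicted = [1, 1, 1, 1, 0, 0, 0] + [1, 1] + [0] * 11
    p, r, f1 = evaluate.paragraph_prf(predicted, reference)
    assert p == pytest.approx(4 / 6)
    assert r == pytest.approx(4 / 7)
    assert f1 == pytest.approx(2 * p * r / (p + r))


def test_prf_degenerate_conventions():
    assert evaluate.paragraph_prf([1, 1], [1, 1]) == (1.0, 1.0, 1.0)
    assert evaluate.paragraph_prf([0, 0], [1, 0]) == (0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        evaluate.paragraph_prf([1], [1, 0])


def test_topn_match_rank_sensitivity():
    p = pred("a", [NormValue.date(2015), NormValue.date(2009), NormValue.date(1998)])
    r = ref("a", [NormValue.date(2009)])
    assert evaluate.topn_match(p, r, 3)
    assert not evaluate.topn_match(p, r, 1)
    assert not evaluate.topn_match(pred("a", []), r, 3)


def test_topn_cross_kind_needs_birth_year():
    p = pred("a", [NormValue.date(2006)])
    r = ref("a", [NormValue.age(16)])
    assert not evaluate.topn_match(p, r, 1)
    assert evaluate.topn_match(p, r, 1, birth_year=1990)


def test_topn_monotone_and_matches_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(1000):
        values = [NormValue.date(int(y)) for y in rng.integers(2000, 2012, size=rng.integers(0, 6))]
        refs = [NormValue.date(int(y)) for y in rng.integers(2000, 2012, size=rng.integers(1, 3))]
        p = pred("a", values, probs=list(rng.random(len(values))))
        r = ref("a", refs)
        results = [evaluate.topn_match(p, r, n) for n in (1, 2, 3, 5)]
        for earlier, later in zip(results, results[1:]):
            assert later or not earlier  # monotone in n
        brute = any(
            c.value.year == rv.year for c in p.candidates[:3] for rv in refs
        )
        assert results[2] == brute


def test_precision_recall_at_n_examples():
    predictions = {"a": pred("a", [NormValue.date(2009)])}
    references = {"a": ref("a", [NormValue.date(2009)])}
    assert evaluate.precision_recall_at_n(predictions, references, 3) == (1.0, 1.0)
    assert evaluate.precision_recall_at_n({}, references, 3) == (0.0, 0.0)


def test_precision_recall_at_n_matches_hand_computation():
    predictions = {
        "a": pred("a", [NormValue.date(2009), NormValue.date(2011)]),
        "b": pred("b", [NormValue.date(2001)]),
        "c": pred("c", []),
    }
    references = {
        "a": ref("a", [NormValue.date(2009), NormValue.date(2011)]),
        "b": ref("b", [NormValue.date(2005)]),
        "c": ref("c", [NormValue.date(2000)]),
    }
    p, r = evaluate.precision_recall_at_n(predictions, references, 3)
    # a: 2/2 and 2/2; b: 0/1 and 0/1; c: 0 and 0
    assert p == pytest.approx((1.0 + 0.0 + 0.0) / 3)
    assert r == pytest.approx((1.0 + 0.0 + 0.0) / 3)


def test_relative_match():
    assert evaluate.relative_match(22, 26) == pytest.approx(0.846, abs=5e-4)
    assert evaluate.relative_match(5, 5) == 1.0
    with pytest.raises(ValueError):
        evaluate.relative_match(1, 0)


def _mention(doc, span, ti=TimeInformation.PAST_ANCHORED, annotator="A"):
    value = NormValue.date(2010) if ti is TimeInformation.PAST_ANCHORED else None
    return OnsetMention(doc, span, ti, value, ClinicalType.SYMPTOM, annotator)


def _paras(doc, n, width=10):
    return [Paragraph(doc, i, (i * width, (i + 1) * width - 1), "w " * 6) for i in range(n)]


def test_iaa_paragraph_limits_and_symmetry():
    paragraphs = _paras("d", 4)
    a = [_mention("d", (1, 4)), _mention("d", (12, 15))]
    b_same = [_mention("d", (2, 6), annotator="B"), _mention("d", (11, 14), annotator="B")]
    assert evaluate.iaa_paragraph(a, b_same, paragraphs) == 1.0
    b_disjoint = [_mention("d", (31, 34), annotator="B")]
    assert evaluate.iaa_paragraph(a, b_disjoint, paragraphs) == 0.0
    b_partial = [_mention("d", (2, 6), annotator="B"), _mention("d", (31, 34), annotator="B")]
    # A marks {0,1}, B marks {0,3}: TP=1, FN=1, FP=1 -> F1 = 2/4
    assert evaluate.iaa_paragraph(a, b_partial, paragraphs) == pytest.approx(0.5)
    assert evaluate.iaa_paragraph(b_partial, a, paragraphs) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        evaluate.iaa_paragraph([_mention("other", (0, 2))], b_same, paragraphs)


def test_iaa_attribute_agreement_fractions():
    PA, PN = TimeInformation.PAST_ANCHORED, TimeInformation.PAST_NOT_ANCHORED
    a = [_mention("d", (0, 5), PA), _mention("d", (10, 15), PA), _mention("d", (20, 25), PN)]
    b = [
        _mention("d", (1, 6), PA, annotator="B"),
        _mention("d", (11, 16), PN, annotator="B"),
        _mention("d", (21, 26), PN, annotator="B"),
    ]
    scores = evaluate.iaa_attribute(a, b, "time_information")
    # pairs: (PA,PA) (PA,PN) (PN,PN) -> PA: 1 of 2; PN: 1 of 2
    assert scores["PAST_ANCHORED"] == pytest.approx(0.5)
    assert scores["PAST_NOT_ANCHORED"] == pytest.approx(0.5)
    assert evaluate.iaa_attribute([], [], "time_information") == {}


def test_patient_time_label_precedence_exhaustive():
    order = [
        TimeInformation.PAST_ANCHORED,
        TimeInformation.PAST_NOT_ANCHORED,
        TimeInformation.CURRENT,
    ]
    for subset in chain.from_iterable(combinations(order, k) for k in range(1, 4)):
        mentions = [_mention("d", (i * 5, i * 5 + 3), ti) for i, ti in enumerate(subset)]
        expected = next(ti for ti in order if ti in subset)
        assert evaluate.patient_time_label(mentions) is expected
    assert evaluate.patient_time_label([]) is None


def test_patient_level_agreement():
    PA, CU = TimeInformation.PAST_ANCHORED, TimeInformation.CURRENT
    a = {"p1": [_mention("d", (0, 3), PA)], "p2": [_mention("d", (0, 3), CU)]}
    b = {"p1": [_mention("d", (5, 8), PA, "B")], "p2": [_mention("d", (5, 8), PA, "B")]}
    assert evaluate.patient_level_agreement(a, b) == 0.5


def test_summarize_dup_two_groups():
    dups = {"a": [3], "b": [1, 5], "c": [2, 8], "d": [0]}
    groups = {"a": "FEP", "b": "FEP", "c": "OTHER", "d": "OTHER"}
    frame = evaluate.summarize_dup(dups, groups).set_index("group")
    assert frame.loc["FEP", "patients"] == 2
    assert frame.loc["FEP", "dup_min_mean"] == pytest.approx(2.0)  # (3+1)/2
    assert frame.loc["FEP", "dup_max_mean"] == pytest.approx(4.0)  # (3+5)/2
    assert frame.loc["OTHER", "dup_min_mean"] == pytest.approx(1.0)
    assert frame.loc["OTHER", "dup_max_mean"] == pytest.approx(4.0)
    # single-value patients: min == max, population std of one value is 0
    single = evaluate.summarize_dup({"a": [3]}, {"a": "G"})
    assert single.loc[0, "dup_min_std"] == 0.0
    assert (frame["dup_min_mean"] <= frame["dup_max_mean"]).all()
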