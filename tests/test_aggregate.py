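"""Candidate extraction, ranking, cleaning, DUP and the earliest baseline."""

from datetime import date, timedelta

import numpy as np
import pytest

from onsetnlp import aggregate, segment
from onsetnlp.aggregate import CandidateDate, CleanConfig, PatientPrediction
from onsetnlp.corpus import NormValue, PatientMeta
from onsetnlp.segment import Paragraph


def cand(value, prob, doc_date=date(2015, 1, 1), source=("d", 0), sentence=""):
    return CandidateDate(
        patient_id="p", value=value, probability=prob, source=source,
        document_date=doc_date, source_sentence=sentence,
    )


def test_extract_candidates_earliest_date_and_age():
    text = "He was seen since Nov 2015. Trouble began in 2009 when he was 19."
    p = Paragraph("d", 0, (0, len(text)), text)
    segment.attach_expressions([p], date(2016, 3, 1))
    out = aggregate.extract_candidates(p, 0.8, "p", date(2016, 3, 1))
    values = {c.value.render() for c in out}
    assert values == {"2009", "AGE19Y"}
    assert all(c.probability == 0.8 for c in out)
    # the source sentence is the one containing the chosen expression
    date_cand = next(c for c in out if c.value.kind == "DATE")
    assert "2009" in date_cand.source_sentence


def test_extract_candidates_duration_only_is_empty():
    text = "He has been unwell for the past six months now."
    p = Paragraph("d", 0, (0, len(text)), text)
    segment.attach_expressions([p], date(2016, 3, 1))
    assert aggregate.extract_candidates(p, 0.9, "p", date(2016, 3, 1)) == []


def test_rank_dedup_and_sort():
    pred = aggregate.rank_patient(
        [
            cand(NormValue.date(2009), 0.9),
            cand(NormValue.date(2009), 0.4),
            cand(NormValue.date(2012), 0.7),
        ]
    )
    assert [(c.value.render(), c.probability) for c in pred.candidates] == [
        ("2009", 0.9),
        ("2012", 0.7),
    ]
    assert aggregate.rank_patient([]).candidates == []


def _brute_force_rank(cands):
    best = {}
    for c in cands:
        k = c.value.render()
        if k not in best or (
            (-c.probability, c.document_date.toordinal(), c.source)
            < (-best[k].probability, best[k].document_date.toordinal(), best[k].source)
        ):
            best[k] = c
    return sorted(
        best.values(),
        key=lambda c: (-c.probability, c.document_date.toordinal(), c.value.sort_key()),
    )


def test_rank_matches_brute_force_and_is_order_invariant():
    rng = np.random.default_rng(12)
    for _ in range(500):
        cands = []
        for _ in range(int(rng.integers(0, 10))):
            if rng.random() < 0.7:
                v = NormValue.date(int(rng.integers(1995, 2016)))
            else:
                v = NormValue.age(int(rng.integers(10, 40)))
            cands.append(
                cand(
                    v,
                    float(rng.choice([0.3, 0.5, 0.7, 0.9])),
                    date(2010, 1, 1) + timedelta(days=int(rng.integers(0, 900))),
                    source=("d", int(rng.integers(0, 5))),
                )
            )
        got = aggregate.rank_patient(cands).candidates
        assert got == _brute_force_rank(cands)
        rng.shuffle(cands)
        assert aggregate.rank_patient(cands).candidates == got
        probs = [c.probability for c in got]
        assert probs == sorted(probs, reverse=True)


def _meta(referral=date(2013, 2, 1), dob=date(1990, 5, 1)):
    return PatientMeta(patient_id="p", first_referral_date=referral, date_of_birth=dob)


def test_clean_removes_constructed_violations():
    good = cand(NormValue.date(2009), 0.9, sentence="unwell in 2009")
    pred = PatientPrediction(
        "p",
        [
            cand(NormValue.date(1899), 0.95, sentence="born in 1899"),
            good,
            cand(NormValue.date(1983), 0.85, sentence="detained under the Mental Health Act in 1983"),
            cand(NormValue.date(2021), 0.8, sentence="seen in 2021"),
            cand(NormValue.age(22), 0.75, sentence="he is 22"),  # age at referral
            cand(NormValue.date(2008), 0.7, sentence="his mother was unwell in 2008"),
            cand(NormValue.date(2005), 0.6, sentence="bullied in 2005"),
            cand(NormValue.date(2003), 0.5, sentence="moved in 2003"),
            cand(NormValue.date(2001), 0.4, sentence="school in 2001"),
        ],
    )
    cleaned = aggregate.clean_candidates(pred, _meta())
    assert [c.value.render() for c in cleaned.candidates] == ["2009", "2005", "2003"]


def test_clean_keeps_1983_without_mha_sentence():
    pred = PatientPrediction("p", [cand(NormValue.date(1983), 0.9, sentence="unwell since 1983")])
    assert len(aggregate.clean_candidates(pred, _meta()).candidates) == 1


def test_clean_skips_age_rule_without_dob():
    meta = PatientMeta(patient_id="p", first_referral_date=date(2013, 2, 1))
    pred = PatientPrediction("p", [cand(NormValue.age(22), 0.9, sentence="he is 22")])
    assert len(aggregate.clean_candidates(pred, meta).candidates) == 1


def test_clean_truncates_to_three():
    pred = aggregate.rank_patient(
        [cand(NormValue.date(2000 + i), 0.9 - i * 0.1, sentence="x") for i in range(5)]
    )
    assert len(aggregate.clean_candidates(pred, _meta()).candidates) == 3


def test_clean_output_subset_of_input():
    rng = np.random.default_rng(3)
    for _ in range(50):
        cands = [
            cand(NormValue.date(int(rng.integers(1880, 2030))), float(rng.random()),
                 sentence="x")
            for _ in range(int(rng.integers(0, 8)))
        ]
        pred = aggregate.rank_patient(cands)
        cleaned = aggregate.clean_candidates(pred, _meta())
        assert len(cleaned.candidates) <= 3
        assert set(c.value.render() for c in cleaned.candidates) <= set(
            c.value.render() for c in pred.candidates
        )


@pytest.mark.parametrize(
    "value,expected",
    [
        (NormValue.date(2009), 3),
        (NormValue.date(2013), 0),  # -1 reported as 0
        (NormValue.age(16), 6),  # DOB 1990 -> onset 2006, referral 2012
    ],
)
def test_compute_dup(value, expected):
    meta = PatientMeta(
        patient_id="p", first_referral_date=date(2012, 6, 1), date_of_birth=date(1990, 5, 1)
    )
    assert aggregate.compute_dup(value, meta) == expected


def test_compute_dup_errors():
    meta = PatientMeta(patient_id="p", first_referral_date=date(2012, 6, 1))
    with pytest.raises(ValueError):
        aggregate.compute_dup(NormValue.age(16), meta)  # no DOB
    with pytest.raises(ValueError):
        aggregate.compute_dup(NormValue.date(2014), meta)  # 2 years after referral


def test_baseline_earliest():
    cands = [cand(NormValue.date(y), 0.5) for y in (2012, 2009, 2001, 1998)]
    assert [v.render() for v in aggregate.baseline_earliest(cands)] == ["1998", "2001", "2009"]
    assert aggregate.baseline_earliest([cand(NormValue.age(20), 0.5)]) == []
    rng = np.random.default_rng(8)
    for _ in range(100):
        years = rng.integers(1950, 2020, size=int(rng.integers(0, 10)))
        cands = [cand(NormValue.date(int(y)), 0.5) for y in years]
        got = [v.year for v in aggregate.baseline_earliest(cands)]
        assert got == sorted(set(int(y) for y in years))[:3]
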