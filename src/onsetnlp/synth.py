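"""Synthetic ground-truthed clinical corpus generator.

Emulates the statistical structure of a first-referral mental-health EHR
extraction so every pipeline stage can be exercised without restricted
data: multiple HTML-paragraph documents per patient (mean 2.4) dated
within three months of the first referral, ~7% positive-paragraph
prevalence after paragraph filtering, a 60/22/18 past-anchored /
past-not-anchored / current mention mix, a 51/25/24 symptom / diagnosis /
non-specific type mix, and distractor paragraphs referencing non-onset
clinical events (admissions, appointments, "seen by this team since
...", family history, current mental state).

Onset sentences are realised from template banks parameterised by
clinical type and value kind; every planted positive paragraph contains
exactly the temporal expression carrying its true onset value, using only
surface forms the rule-based tagger supports, so running the tagger and
the paragraph labeller over a generated corpus recovers the planted
labels exactly.  Every planted onset predates the patient's referral, so
date cleaning never removes a true candidate.  Generation is fully
seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np

from .corpus import (
    ClinicalType,
    Document,
    NormValue,
    OnsetMention,
    PatientMeta,
    TimeInformation,
)

#: symptom vocabulary used by the template banks; doubles as a default
#: keyword lexicon for the document filter when none is supplied
SYMPTOM_KEYWORDS = [
    "voices", "hallucination", "hallucinations", "paranoid", "paranoia",
    "delusional", "delusions", "psychosis", "psychotic", "schizophrenia",
    "persecutory", "thought disorder", "unwell",
]

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
]


@dataclass(frozen=True)
class GenConfig:
    """Study-condition parameters for corpus generation.

    Defaults mirror the reference corpus statistics: 2.4 documents per
    patient, 7% positive-paragraph prevalence, 60/22/18 time-information
    mix, 51/25/24 clinical-type mix, 72% of patients with a past-anchored
    onset, and roughly ten temporal expressions per document (scaled down
    from the 65.6 of full-length referral attachments to desk-scale
    documents).
    """

    n_patients: int = 100
    docs_per_patient_mean: float = 2.4
    positive_paragraph_prevalence: float = 0.07
    time_info_mix: Tuple[float, float, float] = (0.60, 0.22, 0.18)
    type_mix: Tuple[float, float, float] = (0.51, 0.25, 0.24)
    expressions_per_doc_mean: float = 10.0
    onset_lag_years: Tuple[int, int] = (1, 12)
    fep_lag_years: Tuple[int, int] = (0, 3)
    p_anchored_patient: float = 0.72
    conflict_fraction: float = 0.30
    echo_fraction: float = 0.25
    extra_mention_fraction: float = 0.45
    age_value_fraction: float = 0.35
    ambiguous_fraction: float = 0.30
    hard_negative_fraction: float = 0.35
    fep_fraction: float = 0.25
    referral_start: date = date(2013, 1, 1)
    referral_end: date = date(2019, 12, 31)
    age_at_referral: Tuple[int, int] = (18, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.docs_per_patient_mean < 1:
            raise ValueError("docs_per_patient_mean must be >= 1")
        if not 0 < self.positive_paragraph_prevalence < 1:
            raise ValueError("positive_paragraph_prevalence must be in (0, 1)")
        for mix in (self.time_info_mix, self.type_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mix {mix} does not sum to 1")
        if self.p_anchored_patient <= 0:
            raise ValueError(
                "positive prevalence requires some patients with an anchored onset"
            )


@dataclass
class PatientTruth:
    patient_id: str
    date_of_birth: date
    first_referral_date: date
    team: str
    anchored: bool
    onset_values: Dict[ClinicalType, NormValue] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Planted truth: per-patient onsets, per-paragraph labels, expressions."""

    patients: Dict[str, PatientTruth] = field(default_factory=dict)
    labels: Dict[str, List[int]] = field(default_factory=dict)  # doc_id -> labels
    # doc_id -> [(paragraph_index, expected rendered value or None)]
    expressions: Dict[str, List[Tuple[int, Optional[str]]]] = field(default_factory=dict)


@dataclass
class SyntheticCorpus:
    documents: List[Document]
    annotations: List[OnsetMention]
    patient_meta: List[PatientMeta]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Template banks (plain strings with {slots}; temporal phrase included)
# ---------------------------------------------------------------------------

ONSET_TEMPLATES = {
    (ClinicalType.SYMPTOM, "DATE"): [
        "{Pron} first started hearing voices {DATEPHRASE} and became increasingly paranoid.",
        "{Pron} reports that the voices first began {DATEPHRASE}, while {pron} was living with family.",
        "{Pron} first experienced auditory hallucinations {DATEPHRASE}.",
        "Onset of persecutory delusions dates back to {DATEPHRASE_BARE}, with voices developing thereafter.",
    ],
    (ClinicalType.SYMPTOM, "AGE"): [
        "{Pron} started hearing voices {AGEPHRASE}.",
        "{Pron} says this presence has been around since {AGEPHRASE_BARE}.",
        "{Pron} first became paranoid {AGEPHRASE}.",
        "The voices reportedly first appeared {AGEPHRASE}.",
    ],
    (ClinicalType.DIAGNOSIS, "DATE"): [
        "{Pron} was first diagnosed with paranoid schizophrenia {DATEPHRASE} while living abroad.",
        "{Pron} received a diagnosis of schizophrenia {DATEPHRASE} from a previous mental health service.",
        "A first episode of psychosis was documented {DATEPHRASE}.",
    ],
    (ClinicalType.DIAGNOSIS, "AGE"): [
        "{Pron} was first diagnosed with schizophrenia {AGEPHRASE}.",
        "{Pron} had a first psychotic episode {AGEPHRASE}.",
    ],
    (ClinicalType.NON_SPECIFIC, "DATE"): [
        "The family noticed a marked change in {poss} behaviour {DATEPHRASE}.",
        "Things reportedly started to go wrong {DATEPHRASE}, when {pron} became withdrawn and suspicious.",
        "{Pron} first became unwell {DATEPHRASE} according to collateral history.",
    ],
    (ClinicalType.NON_SPECIFIC, "AGE"): [
        "{Pron} first became unwell {AGEPHRASE}.",
        "{Poss} behaviour reportedly changed {AGEPHRASE}.",
    ],
}

# Lexically ambiguous pairs: an onset statement and a current-presentation
# statement sharing the same token stream apart from the date itself.  These
# emulate the overlap between past-onset and current-symptomatology language
# that makes real paragraph classification hard under class imbalance.
AMBIGUOUS_TEMPLATES = [
    "{Pron} described hearing voices when {pron} was seen in {YEARTOK}.",
    "{Pron} reported paranoid ideas at a review in {YEARTOK}.",
    "Notes mention {pron} experienced persecutory beliefs in {YEARTOK}.",
]

ONSET_PADS = [
    "Collateral history was obtained at the initial assessment.",
    "This was followed by increasing social withdrawal and self neglect.",
    "There had been no contact with services before that point.",
    "{Pron} described a gradual decline in functioning around that time.",
]

PNA_TEMPLATES = [
    "There is a long history of delusional beliefs with unclear onset.",
    "{Pron} has struggled with paranoid ideas for many years.",
    "Longstanding history of hearing voices, exact onset unclear.",
]

CURRENT_TEMPLATES_PLAIN = [
    "On assessment {pron} presented with auditory hallucinations and thought disorder.",
    "{Pron} is currently responding to unseen stimuli and appears guarded.",
    "This presentation is clearly a first episode of psychosis.",
]

CURRENT_TEMPLATES_DURATION = [
    "{Pron} reports that {poss} mental state has been stable {DURPHRASE}.",
    "{Pron} has been experiencing worsening voices {DURPHRASE}.",
]

DISTRACTOR_RECENT = [
    "{Pron} was admitted to the ward on {DMY} following a deterioration in {poss} mental state.",
    "{Pron} attended an outpatient appointment on {DMY} with the care coordinator.",
    "I have known this patient since {MONYEAR}, when {pron} was first seen by this team.",
    "{Pron} was started on risperidone in {MONYEAR} with partial response.",
    "The care plan was reviewed on {DMY} with the community team.",
    "A referral letter was received by our service in {MONYEAR}.",
]

DISTRACTOR_RECENT_EXTRA = [
    "{Pron} was reviewed again in {MONYEAR2} by the duty doctor.",
    "A follow up appointment was arranged for {DMY2}.",
]

DISTRACTOR_EARLY_LIFE = [
    "{Pron} was diagnosed with depression in {YEAR} and saw a counsellor for several months.",
    "{Pron} experienced significant bullying at school in {YEAR}.",
    "The family moved to London in {YEAR}, which {pron} found very stressful.",
    "{Pron} was treated for low mood in {YEAR} by the GP.",
]

DISTRACTOR_RELATIVE = [
    "{Poss} mother was diagnosed with schizophrenia in {YEAR}.",
    "{Poss} brother has a history of psychosis and was admitted in {YEAR}.",
    "{Poss} father received treatment for depression in {YEAR}.",
]

DISTRACTOR_DURATION = [
    "{Pron} has been sleeping poorly {DURPHRASE}.",
    "{Pron} has not taken any medication {DURPHRASE}.",
]

FILLER_TEMPLATES = [
    "Medication was reviewed and no changes were made at this time.",
    "{Pron} lives alone and is currently unemployed.",
    "There were no concerns regarding risk to self or to others.",
    "{Pron} was pleasant and cooperative throughout the interview.",
    "No physical health problems were reported at assessment.",
]

HEADER_TEMPLATES = [
    "Mental state examination:",
    "Past psychiatric history:",
    "Plan:",
    "Current medication:",
]

OPENING_TEMPLATES = [
    "Thank you for referring this patient to our community mental health service.",
    "I reviewed this patient together with the team at the clinic today.",
    "This letter summarises the initial assessment of this patient by our team.",
]

_NUM_WORDS = ["one", "two", "three", "four", "five", "six", "seven", "eight", "nine"]

_TIME_LEVELS = [
    TimeInformation.PAST_ANCHORED,
    TimeInformation.PAST_NOT_ANCHORED,
    TimeInformation.CURRENT,
]
_TYPE_LEVELS = [ClinicalType.SYMPTOM, ClinicalType.DIAGNOSIS, ClinicalType.NON_SPECIFIC]


def _pick(rng, bank):
    return bank[int(rng.integers(len(bank)))]


def _dmy(rng, d: date) -> str:
    return f"{d.day} {_MONTH_NAMES[d.month - 1]} {d.year}"


def _monyear(d: date) -> str:
    return f"{_MONTH_NAMES[d.month - 1][:3]} {d.year}"


def _age_phrase(rng, age: int) -> str:
    forms = [f"at the age of {age}", f"when {{pron}} was {age}", f"aged {age}"]
    return _pick(rng, forms)


def _date_phrase(rng, year: int) -> Tuple[str, str]:
    """(phrase with preposition, rendered value) for a year-granular onset."""
    r = rng.integers(3)
    if r == 0:
        return f"in {year}", str(year)
    if r == 1:
        month = int(rng.integers(1, 13))
        return f"in {_MONTH_NAMES[month - 1]} {year}", str(year)
    return f"around {year}", str(year)


def _dur_phrase(rng) -> str:
    n = int(rng.integers(2, 10))
    unit = _pick(rng, ["weeks", "months"])
    return f"for the past {_NUM_WORDS[n - 1]} {unit}"


def _fill_pronouns(text: str, pron: str) -> str:
    poss = {"he": "his", "she": "her", "they": "their"}[pron]
    return (
        text.replace("{Pron}", pron.capitalize())
        .replace("{pron}", pron)
        .replace("{Poss}", poss.capitalize())
        .replace("{poss}", poss)
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _rand_date(rng, start: date, end: date) -> date:
    return start + timedelta(days=int(rng.integers((end - start).days + 1)))


def _make_patients(rng, config: GenConfig) -> List[PatientTruth]:
    patients = []
    for i in range(config.n_patients):
        referral = _rand_date(rng, config.referral_start, config.referral_end)
        age_ref = int(rng.integers(config.age_at_referral[0], config.age_at_referral[1] + 1))
        dob = referral - timedelta(days=int(age_ref * 365.25 + rng.integers(0, 300)))
        team = "FEP" if rng.random() < config.fep_fraction else "CMHT"
        anchored = bool(rng.random() < config.p_anchored_patient)
        patients.append(
            PatientTruth(
                patient_id=f"P{i:04d}",
                date_of_birth=dob,
                first_referral_date=referral,
                team=team,
                anchored=anchored,
            )
        )
    return patients


def _plan_mentions(rng, config: GenConfig, patient: PatientTruth) -> List[dict]:
    """Plan this patient's anchored onset mention events (value + type)."""
    if not patient.anchored:
        return []
    referral_year = patient.first_referral_date.year
    birth_year = patient.date_of_birth.year
    lag_lo, lag_hi = (
        config.fep_lag_years if patient.team == "FEP" else config.onset_lag_years
    )
    lag_hi = min(lag_hi, referral_year - birth_year - 13)
    lag = int(rng.integers(lag_lo, max(lag_lo, lag_hi) + 1))
    onset_year = referral_year - lag
    # ages are only used for onsets at least a year before referral, so the
    # current-age cleaning rule can never remove a true candidate
    use_age = bool(rng.random() < config.age_value_fraction) and lag >= 1

    def to_value(year: int) -> NormValue:
        if use_age:
            return NormValue.age(year - birth_year)
        return NormValue.date(year)

    events = []
    n_mentions = 1 + int(rng.random() < config.extra_mention_fraction)
    years = [onset_year] + [
        min(onset_year + int(rng.integers(0, 4)), referral_year)
        for _ in range(n_mentions - 1)
    ]
    for year in years:
        ctype = _TYPE_LEVELS[int(rng.choice(3, p=config.type_mix))]
        events.append({"kind": "ANCH", "type": ctype, "value": to_value(year), "year": year})
    if rng.random() < config.conflict_fraction:
        base = events[int(rng.integers(len(events)))]
        year = min(base["year"] + int(rng.integers(1, 4)), referral_year)
        events.append(
            {"kind": "ANCH", "type": base["type"], "value": to_value(year), "year": year}
        )
    if rng.random() < config.echo_fraction:
        base = events[int(rng.integers(len(events)))]
        events.append(dict(base))
    # the true onset per type is the earliest planted value of that type
    for ev in events:
        current = patient.onset_values.get(ev["type"])
        if current is None or ev["value"].sort_key() < current.sort_key():
            patient.onset_values[ev["type"]] = ev["value"]
    return events


def _realize_onset(rng, ev: dict, pron: str, ambiguous_fraction: float) -> Tuple[str, Optional[str]]:
    kind = "AGE" if ev["value"].kind == "AGE" else "DATE"
    if kind == "DATE" and rng.random() < ambiguous_fraction:
        text = _pick(rng, AMBIGUOUS_TEMPLATES).replace("{YEARTOK}", str(ev["value"].year))
        return _fill_pronouns(text, pron), str(ev["value"].year)
    template = _pick(rng, ONSET_TEMPLATES[(ev["type"], kind)])
    if kind == "AGE":
        phrase = _age_phrase(rng, ev["value"].age_years)
        bare = f"the age of {ev['value'].age_years}"
        text = template.replace("{AGEPHRASE_BARE}", bare).replace("{AGEPHRASE}", phrase)
        rendered = ev["value"].render()
    else:
        phrase, rendered = _date_phrase(rng, ev["value"].year)
        text = template.replace("{DATEPHRASE_BARE}", phrase.split(" ", 1)[1]).replace(
            "{DATEPHRASE}", phrase
        )
    return _fill_pronouns(text, pron), rendered


def _realize_distractor(
    rng, category: str, pron: str, doc_date: date, patient: PatientTruth, extra: bool
) -> Tuple[str, List[Optional[str]]]:
    """Realise one distractor paragraph; returns (text, expected values)."""
    birth_year = patient.date_of_birth.year
    onset_years = [
        v.year if v.kind == "DATE" else birth_year + v.age_years
        for v in patient.onset_values.values()
    ]
    early_hi = (min(onset_years) if onset_years else doc_date.year - 3) - 1
    early_lo = birth_year + 8
    if category in ("early", "relative") and early_lo >= early_hi:
        category = "recent"
    if category == "hard":
        year = doc_date.year - int(rng.integers(0, 2))
        text = _pick(rng, AMBIGUOUS_TEMPLATES).replace("{YEARTOK}", str(year))
        return _fill_pronouns(text, pron), [str(year)]
    if category == "recent":
        d1 = doc_date - timedelta(days=int(rng.integers(-45, 400)))
        template = _pick(rng, DISTRACTOR_RECENT)
        text = template.replace("{DMY}", _dmy(rng, d1)).replace("{MONYEAR}", _monyear(d1))
        values = [NormValue.date(d1.year, d1.month, d1.day).render()
                  if "{DMY}" in template else NormValue.date(d1.year, d1.month).render()]
        if extra:
            d2 = d1 + timedelta(days=int(rng.integers(10, 120)))
            extra_t = _pick(rng, DISTRACTOR_RECENT_EXTRA)
            text += " " + extra_t.replace("{MONYEAR2}", _monyear(d2)).replace(
                "{DMY2}", _dmy(rng, d2)
            )
            values.append(
                NormValue.date(d2.year, d2.month, d2.day).render()
                if "{DMY2}" in extra_t
                else NormValue.date(d2.year, d2.month).render()
            )
    elif category == "early":
        year = int(rng.integers(early_lo, early_hi + 1))
        text = _pick(rng, DISTRACTOR_EARLY_LIFE).replace("{YEAR}", str(year))
        values = [str(year)]
    elif category == "relative":
        year = int(rng.integers(early_lo, early_hi + 1))
        text = _pick(rng, DISTRACTOR_RELATIVE).replace("{YEAR}", str(year))
        values = [str(year)]
    else:  # duration
        text = _pick(rng, DISTRACTOR_DURATION).replace("{DURPHRASE}", _dur_phrase(rng))
        values = [None]
    return _fill_pronouns(text, pron), values


def generate(config: GenConfig) -> SyntheticCorpus:
    """Generate a corpus, standoff annotations, metadata and ground truth."""
    rng = np.random.default_rng(config.seed)
    patients = _make_patients(rng, config)
    pron_of = {p.patient_id: _pick(rng, ["he", "she"]) for p in patients}

    # plan anchored mention events, then past-not-anchored / current events
    # with rates derived from the configured mix
    events_of: Dict[str, List[dict]] = {}
    n_anchored_events = 0
    for p in patients:
        events_of[p.patient_id] = _plan_mentions(rng, config, p)
        n_anchored_events += len(events_of[p.patient_id])
    w_anch, w_pna, w_cur = config.time_info_mix
    mean_anch = n_anchored_events / config.n_patients
    for p in patients:
        for _ in range(int(rng.poisson(mean_anch * w_pna / w_anch))):
            ctype = _TYPE_LEVELS[int(rng.choice(3, p=config.type_mix))]
            events_of[p.patient_id].append({"kind": "PNA", "type": ctype, "value": None})
        for _ in range(int(rng.poisson(mean_anch * w_cur / w_anch))):
            ctype = _TYPE_LEVELS[int(rng.choice(3, p=config.type_mix))]
            has_dur = bool(rng.random() < 0.5)
            events_of[p.patient_id].append(
                {"kind": "CUR", "type": ctype, "value": None, "dur": has_dur}
            )

    # document shells and event -> document assignment
    doc_shells = []  # (patient, doc_id, doc_date, [events])
    for p in patients:
        n_docs = 1 + int(rng.poisson(config.docs_per_patient_mean - 1))
        shells = []
        for j in range(n_docs):
            doc_id = f"{p.patient_id}_D{j}"
            doc_date = p.first_referral_date + timedelta(days=int(rng.integers(0, 91)))
            shells.append((p, doc_id, doc_date, []))
        for ev in events_of[p.patient_id]:
            shells[int(rng.integers(n_docs))][3].append(ev)
        doc_shells.extend(shells)

    # distractor budget from the target positive prevalence
    n_pos = n_anchored_events
    n_cur_dur = sum(
        1 for evs in events_of.values() for ev in evs if ev["kind"] == "CUR" and ev.get("dur")
    )
    target_retained = int(round(n_pos / config.positive_paragraph_prevalence))
    n_distract = max(0, target_retained - n_pos - n_cur_dur)
    alloc = rng.multinomial(n_distract, np.full(len(doc_shells), 1.0 / len(doc_shells)))

    # extra second-date sentences in recent distractors to approach the
    # configured expressions-per-document mean
    base_expr = n_pos + n_cur_dur + n_distract
    target_expr = config.expressions_per_doc_mean * len(doc_shells)
    recent_share = 0.55 * (1 - config.hard_negative_fraction)
    extra_p = float(np.clip((target_expr - base_expr) / max(1.0, recent_share * n_distract), 0, 1))

    documents: List[Document] = []
    annotations: List[OnsetMention] = []
    truth = GroundTruth(patients={p.patient_id: p for p in patients})

    for (p, doc_id, doc_date, events), n_d in zip(doc_shells, alloc):
        pron = pron_of[p.patient_id]
        # plan paragraphs: (text, label, mention(sentence-local span info), values)
        plan = []
        if rng.random() < 0.6:
            plan.append({"text": _fill_pronouns(_pick(rng, OPENING_TEMPLATES), pron),
                         "label": 0, "mention": None, "values": []})
        for ev in events:
            if ev["kind"] == "ANCH":
                sentence, rendered = _realize_onset(rng, ev, pron, config.ambiguous_fraction)
                parts, m_idx = [sentence], 0
                if rng.random() < 0.5:
                    parts.insert(0, _fill_pronouns(_pick(rng, ONSET_PADS), pron))
                    m_idx = 1
                if rng.random() < 0.3:
                    parts.append(_fill_pronouns(_pick(rng, ONSET_PADS), pron))
                offset = sum(len(s) + 1 for s in parts[:m_idx])
                plan.append(
                    {
                        "text": " ".join(parts),
                        "label": 1,
                        "mention": {
                            "local": (offset, offset + len(sentence)),
                            "time": TimeInformation.PAST_ANCHORED,
                            "type": ev["type"],
                            "value": ev["value"],
                        },
                        "values": [rendered],
                    }
                )
            elif ev["kind"] == "PNA":
                sentence = _fill_pronouns(_pick(rng, PNA_TEMPLATES), pron)
                plan.append(
                    {
                        "text": sentence,
                        "label": 0,
                        "mention": {
                            "local": (0, len(sentence)),
                            "time": TimeInformation.PAST_NOT_ANCHORED,
                            "type": ev["type"],
                            "value": None,
                        },
                        "values": [],
                    }
                )
            else:  # CURRENT
                bank = CURRENT_TEMPLATES_DURATION if ev.get("dur") else CURRENT_TEMPLATES_PLAIN
                sentence = _fill_pronouns(
                    _pick(rng, bank).replace("{DURPHRASE}", _dur_phrase(rng)), pron
                )
                plan.append(
                    {
                        "text": sentence,
                        "label": 0,
                        "mention": {
                            "local": (0, len(sentence)),
                            "time": TimeInformation.CURRENT,
                            "type": ev["type"],
                            "value": None,
                        },
                        "values": [None] if ev.get("dur") else [],
                    }
                )
        for _ in range(int(n_d)):
            category = _pick_category(rng, config.hard_negative_fraction)
            extra = category == "recent" and rng.random() < extra_p
            text, values = _realize_distractor(rng, category, pron, doc_date, p, extra)
            plan.append({"text": text, "label": 0, "mention": None, "values": values})
        for _ in range(int(rng.integers(1, 4))):
            plan.append({"text": _fill_pronouns(_pick(rng, FILLER_TEMPLATES), pron),
                         "label": 0, "mention": None, "values": []})
        for _ in range(int(rng.integers(0, 3))):
            plan.append({"text": _pick(rng, HEADER_TEMPLATES),
                         "label": 0, "mention": None, "values": []})

        order = rng.permutation(len(plan))
        plan = [plan[i] for i in order]

        # realise raw text with offsets
        pieces, labels, expr_truth = [], [], []
        pos = 0
        for idx, para in enumerate(plan):
            prefix, suffix = "<p>", "</p>\n"
            start = pos + len(prefix)
            pieces.append(prefix + para["text"] + suffix)
            if para["mention"] is not None:
                lo, hi = para["mention"]["local"]
                annotations.append(
                    OnsetMention(
                        doc_id=doc_id,
                        span=(start + lo, start + hi),
                        time_information=para["mention"]["time"],
                        value=para["mention"]["value"],
                        clinical_type=para["mention"]["type"],
                    )
                )
            labels.append(para["label"])
            for v in para["values"]:
                expr_truth.append((idx, v))
            pos += len(pieces[-1])
        documents.append(
            Document(doc_id=doc_id, patient_id=p.patient_id,
                     document_date=doc_date, text="".join(pieces))
        )
        truth.labels[doc_id] = labels
        truth.expressions[doc_id] = expr_truth

    metas = [
        PatientMeta(
            patient_id=p.patient_id,
            first_referral_date=p.first_referral_date,
            date_of_birth=p.date_of_birth,
            team_labels=frozenset([p.team]),
        )
        for p in patients
    ]
    return SyntheticCorpus(documents, annotations, metas, truth)


def _pick_category(rng, hard_negative_fraction: float) -> str:
    hard = 0.55 * hard_negative_fraction
    return ["recent", "hard", "early", "relative", "duration"][
        int(rng.choice(5, p=[0.55 - hard, hard, 0.25, 0.10, 0.10]))
    ]


def emit_gold_reference(truth: GroundTruth):
    """Patient-level reference values and per-paragraph gold labels."""
    from .corpus import PatientReference

    references = {}
    for pid, p in truth.patients.items():
        references[pid] = PatientReference(patient_id=pid, values=dict(p.onset_values))
    return references, dict(truth.labels)


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "patients": {
            pid: {
                "date_of_birth": p.date_of_birth.isoformat(),
                "first_referral_date": p.first_referral_date.isoformat(),
                "team": p.team,
                "anchored": p.anchored,
                "onset_values": {t.value: v.render() for t, v in p.onset_values.items()},
            }
            for pid, p in truth.patients.items()
        },
        "labels": truth.labels,
        "expressions": {d: [[i, v] for i, v in rows] for d, rows in truth.expressions.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
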