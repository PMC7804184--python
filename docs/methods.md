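# Methods

This note documents the models and procedures implemented in `onsetnlp`,
the parameter defaults and why they were chosen, what the synthetic
corpus generator does and does not emulate, and the numerical and design
choices made where the problem was genuinely open.

## Problem setting

Given, per patient, a set of dated free-text documents written around the
first referral to a mental-health service, the task is to produce a short
ranked list of candidate psychosis-onset dates (calendar years or ages),
from which the duration of untreated psychosis (DUP = referral year −
onset year) can be estimated. The pipeline treats the paragraph as the
unit of analysis: onset statements typically span one or a few sentences
combining a clinical reference (a symptom, a diagnosis, or a non-specific
behavioural change) with a temporal reference, and paragraphs are the
smallest units likely to contain both.

## Temporal tagging

A rule-based tagger extracts four categories of expression and assigns a
normalised value anchored to the document date:

- **absolute dates** — bare years (1900–2099), month-year, day-month-year
  in UK ordering (day before month), numeric `d/m/Y` and `d.m.Y`, ISO
  dates. Granularity follows the surface form (`2012`, `2015-11`,
  `2015-03-12`).
- **relative dates** — "N years/months/weeks/days ago". Year and month
  offsets normalise to month granularity (the anchor's day is not
  meaningful at that distance); week/day offsets to day granularity.
- **ages** — "at the age of N", "aged N", "when/since he/she was N",
  rendered `AGE<n>Y`. Ages above 120 are rejected.
- **durations** — "for (the past/last) N units", in days (year=365,
  month=30, week=7).

"N year history of X" is resolved to a relative date (anchor − N years);
this pattern is a documented weak spot of keyword-driven extraction, so
it is switchable off via `TaggerConfig(resolve_history=False)` for
behaviour faithful to a tagger without the rule. Two-digit years are
deliberately unresolved (ambiguous in clinical text); fuzzy references
("a long time ago") yield nothing. Overlapping matches are resolved
leftmost-longest. The contract of the tagger is pinned by a hand-computed
oracle fixture of 46 (surface, anchor, expected) triples that must pass
exactly.

## Filtering and segmentation

Documents are retained when (a) character length strictly exceeds the
corpus median (configurable percentile; an absolute override exists for
incremental use — the quantile is computed on the corpus passed to the
call), (b) they contain at least one symptom keyword (case-insensitive
word-boundary match against a user-supplied lexicon, no stemming —
inflected variants belong in the lexicon), and (c) they contain more than
five temporal expressions. A funnel report (stage, documents, patients)
is emitted.

Documents are split into paragraphs on block-level HTML tags (`p`, `br`,
`div`, `li`, `tr`, table and heading tags) and, in untagged text, on
blank lines. Paragraph spans are 0-based half-open intervals into the
*raw* text, so standoff annotation offsets remain valid; inline tags are
stripped from paragraph text only. Paragraphs are retained when they have
at least 5 words, are not header-like, and contain at least one temporal
expression. "Header-like" is operationalised as: every physical line has
≤ 3 words, or the paragraph ends with a colon and has ≤ 6 words (both
thresholds configurable); this is a deliberate sharpening of an
informally stated rule.

## Reference standards

A paragraph is labelled positive iff it overlaps a **past-anchored**
onset mention carrying a normalised value; mentions in the other two
time-information categories (past not anchored, current) never produce
labels, because only anchored values support date extraction. Patient
adjudication selects, per clinical type (symptom / diagnosis /
non-specific), the earliest value, comparing dates at year granularity
and ages among ages — at most three reference values per patient. When a
type carries both dates and ages, the type slot keeps the date (directly
usable for DUP) and the earliest age is retained separately; this choice
is ours, made because date/age equivalence is only decidable given a date
of birth.

## Paragraph classifier

Text is tokenised as Unicode word-character runs, lowercased, punctuation
dropped, no stopword removal. Two representations: TF-IDF (minimum
document frequency 5, at most 5000 features) and averaged word vectors
(mean of in-vocabulary token embeddings, zero vector when none; vectors
are read from a whitespace-delimited text file). Optional count features:
word count, symptom-keyword count, temporal-expression count, earliest
date year and longest duration in days — the last two with
missing-indicator columns, all standardised on the training data (years
are large on the scale of TF-IDF weights; standardisation is a numerical
choice, not a modelling claim).

Classifiers: logistic regression (C=1.0, the library default, as no
tuning evidence exists for this task), random forest (100 trees), linear
SVM with Platt-calibrated probabilities. Class imbalance (~7% positive)
is handled either by **random majority subsampling** to a 1:1 ratio
(ratio configurable; all minority examples kept, a uniform random subset
of the majority drawn per seed) or by balanced class weights. The default
configuration is TF-IDF + logistic regression + subsampling, the
configuration that favours recall — the operationally relevant metric,
since a missed onset paragraph cannot be recovered downstream, while a
false positive merely competes in the ranking.

Cross-validation is 5-fold **grouped by patient**: no patient contributes
paragraphs to both sides of any fold, and the featurizer is fitted on
each fold's training portion only. An assertion enforces the empty
train/validation patient intersection.

## Aggregation, cleaning, DUP

From each paragraph at or above the operating threshold (default 0.5; a
keep-all mode ranks every paragraph), at most one date candidate (the
earliest date, reduced to year) and one age candidate (the earliest age)
are extracted, carrying the paragraph probability and the sentence
containing the expression. Per patient: duplicates merge keeping the
highest probability; ranking is by probability descending with
deterministic tie-breaks (earlier document date, then earlier value, with
dates ordered before ages) so the ranking is total and
permutation-invariant.

Cleaning removes: dates before 1900; year-1983 candidates whose source
sentence matches `/mental health act/i` (removing *all* 1983 dates would
be over-broad — the year is only suspicious when the Act is being cited);
age candidates equal to the patient's age at referral (skipped with a
warning when no date of birth is available); candidates whose source
sentence mentions a relative (configurable lexicon: mother, father,
brother, ...); dates after the first referral year. The surviving list is
truncated to three. DUP is computed at year granularity; a value of −1 is
reported as 0 (a one-year error margin, since onset and referral year
granularities overlap), uniformly for date- and age-derived onsets; below
−1 is an error.

## Evaluation

Paragraph precision/recall/F1 use the zero-division-to-zero convention.
Top-N match: a patient (restricted to patients with a non-empty
past-anchored reference) counts as matched when any top-N candidate
equals any reference value — year equality for dates, age equality for
ages, and date↔age cross-matching only when a date of birth permits the
conversion. precision@N divides by `min(N, returned)` so a patient
returning fewer than N candidates is not penalised for list length (the
plain-N convention is available); recall@N divides by the number of
reference values. The relative match divides matched patients under
predicted paragraphs by matched patients under gold paragraphs, isolating
classifier loss from aggregation loss. Agreement: paragraph-level F1
(true positives are paragraphs marked by both annotators; symmetric by
construction), per-value attribute agreement on span-overlapping mention
pairs, and a patient-level label by precedence (past anchored > past not
anchored > current). DUP summaries take each patient's minimum and
maximum DUP and report group-wise count, mean, standard deviation
(population, ddof=0 — the group is the cohort, not a sample) and range.

## Synthetic corpus generator

The generator emulates the *statistical shell* of a first-referral
extraction so that every stage has ground truth:

- ~2.4 documents per patient (1 + Poisson), dated within 90 days after
  referral; referral dates 2013–2019; age at referral 18–45.
- 72% of patients carry a past-anchored onset; onset lag behind referral
  is 0–3 years for FEP-team patients and 1–12 years otherwise (FEP
  services admit at first episode, so short DUP is part of the study
  conditions, and the group contrast is what the DUP summary validates).
- Onset mentions are realised from template banks per clinical type and
  value kind (date or age, 35% ages); types are drawn i.i.d. from the
  51/25/24 mix; past-not-anchored and current mention rates are derived
  from the 60/22/18 mix relative to the realised anchored count. 30% of
  anchored patients get a conflicting secondary value 1–3 years later;
  echoes repeat a mention across documents.
- Distractor paragraphs carry non-onset temporal references: recent
  clinical events (admissions, appointments, "seen by this team since
  ..."), early-life events with mild mental-health vocabulary (pre-onset
  years — these are what break the earliest-dates baseline), family
  history (removed by the relative-cleaning rule), and current-state
  durations. Their number is computed from the target 7% positive
  prevalence among retained paragraphs; extra second-date sentences are
  added to approach ~10 expressions per document (scaled down from the
  65.6 of full-length referral letters to desk-scale documents).
- A fraction of onset sentences (30%) use templates lexically identical
  to a "hard negative" current-presentation bank, differing only in the
  date token. This reproduces the property that makes real paragraph
  classification hard: without it the synthetic classes are linearly
  separable and imbalance handling would be untestable (unweighted
  training would not under-recall, contrary to what imbalanced clinical
  data shows).

Only surface forms supported by the tagger are used, so tagging +
labelling recovers the planted labels exactly, and every planted onset
predates referral so cleaning never removes a true candidate — both are
tested invariants.

**What the generator does not emulate:** realistic clinical language
(templates, not prose), OCR noise, negation/hedging, annotator
disagreement (single gold annotator), vague temporal references, and
documents outside the referral window. Passing tests on synthetic data
therefore demonstrate the *machinery* — correct normalisation, leakage-
free training, correct aggregation arithmetic, and the expected
directional effects of subsampling and ranking — not clinical-grade
accuracy; absolute synthetic scores are upper bounds.

## Problem sizes and determinism

The default experiment uses 250 patients split 200/50 by patient (~5000
retained paragraphs), the distributional self-checks 500 patients; these
sizes make all metrics stable without requiring more than a few seconds
on one CPU. Every stochastic step (generation, splitting, subsampling,
model seeds) flows from a single integer seed; repeated runs are
bit-identical.

## Known limitations

- The tagger's rule inventory is finite; clinical date formats outside it
  (season references, academic years, two-digit years) yield nothing.
- Candidates are reduced to year granularity throughout; month-level DUP
  is out of scope.
- Date↔age cross-matching uses birth year only, so an off-by-one age can
  occur around birthdays.
- The relative-sentence cleaning rule is a keyword heuristic over the
  sentence containing the expression; a relative mentioned in a
  neighbouring sentence escapes it.
- Word-embedding features require user-supplied vectors; no pretrained
  vectors ship with the package.
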