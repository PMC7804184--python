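"""Supervised paragraph classification.

Feature construction (TF-IDF or averaged word embeddings, optional count
features), class-imbalance handling by random majority subsampling or
balanced class weights, model training (logistic regression, random
forest, linear SVM with Platt-calibrated probabilities) and patient-
grouped cross-validation.  scikit-learn provides the estimators; this
module owns the feature pipeline, the subsampling procedure and the
leakage-free fold construction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from scipy import sparse
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import temporal
from .segment import Paragraph, count_keywords

logger = logging.getLogger("onsetnlp")

_TOKEN = re.compile(r"\w+", re.UNICODE)

#: sentinel for absent earliest-date / longest-duration count features;
#: each sentinel column is paired with a missing-indicator column.
_SENTINEL = 0.0


def preprocess(text: str) -> List[str]:
    """Tokenise, lowercase, drop punctuation (Unicode word-character runs)."""
    return _TOKEN.findall(text.lower())


def _identity(x):  # module-level so fitted vectorizers pickle cleanly
    return x


@dataclass(frozen=True)
class FeatureSpec:
    text_mode: str = "TFIDF"  # "TFIDF" | "EMBEDDING"
    tfidf_min_df: int = 5
    tfidf_max_features: int = 5000
    use_counts: bool = False

    def __post_init__(self) -> None:
        if self.text_mode not in ("TFIDF", "EMBEDDING"):
            raise ValueError(f"unknown text_mode {self.text_mode!r}")
        if self.tfidf_min_df < 1 or self.tfidf_max_features < 1:
            raise ValueError("tfidf_min_df and tfidf_max_features must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    algorithm: str = "LR"  # "LR" | "RF" | "SVM"
    imbalance: str = "SUBSAMPLE"  # "SUBSAMPLE" | "CLASS_WEIGHTS" | "NONE"
    seed: int = 0
    cv_folds: int = 5
    subsample_ratio: float = 1.0  # majority:minority ratio after subsampling
    lr_c: float = 1.0
    rf_trees: int = 100
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ("LR", "RF", "SVM"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.imbalance not in ("SUBSAMPLE", "CLASS_WEIGHTS", "NONE"):
            raise ValueError(f"unknown imbalance mode {self.imbalance!r}")


def load_word_vectors(path) -> Dict[str, np.ndarray]:
    """Read whitespace-delimited text word vectors (token then floats).

    A first line consisting of two integers (vocab size, dimension) is
    treated as a header and skipped.
    """
    vectors: Dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip().split()
            if not parts:
                continue
            if i == 0 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue
            vectors[parts[0]] = np.asarray(parts[1:], dtype=float)
    if not vectors:
        raise ValueError(f"no vectors read from {path}")
    return vectors


class ParagraphFeaturizer:
    """Fit/transform feature matrices for paragraphs.

    TFIDF mode excludes terms below ``tfidf_min_df`` document frequency
    and keeps at most ``tfidf_max_features`` terms; EMBEDDING mode
    averages in-vocabulary token vectors (zero row when none).  With
    ``use_counts`` five count features are appended — word count, symptom
    keyword count, temporal-expression count, earliest-date year and
    longest duration in days — the last two with missing indicators, all
    standardised on the fit data.
    """

    def __init__(
        self,
        spec: FeatureSpec,
        vectors: Optional[Dict[str, np.ndarray]] = None,
        lexicon: Sequence[str] = (),
    ):
        self.spec = spec
        self.vectors = vectors
        self.lexicon = list(lexicon)
        if spec.text_mode == "EMBEDDING" and vectors is None:
            raise ValueError("EMBEDDING mode requires a word-vector table")
        self._tfidf: Optional[TfidfVectorizer] = None
        self._scaler: Optional[StandardScaler] = None
        self.vocabulary_: Optional[dict] = None

    # -- text block --------------------------------------------------
    def _embed(self, paragraphs: Sequence[Paragraph]) -> np.ndarray:
        dim = len(next(iter(self.vectors.values())))
        rows = np.zeros((len(paragraphs), dim))
        for i, p in enumerate(paragraphs):
            vecs = [self.vectors[t] for t in preprocess(p.text) if t in self.vectors]
            if vecs:
                rows[i] = np.mean(vecs, axis=0)
        return rows

    # -- count block -------------------------------------------------
    def _counts(self, paragraphs: Sequence[Paragraph]) -> np.ndarray:
        rows = np.zeros((len(paragraphs), 7))
        for i, p in enumerate(paragraphs):
            ed = temporal.earliest_date(p.expressions)
            dur = temporal.longest_duration(p.expressions)
            rows[i] = [
                p.word_count,
                count_keywords(p.text, self.lexicon) if self.lexicon else 0,
                len(p.expressions),
                ed.year if ed is not None else _SENTINEL,
                1.0 if ed is None else 0.0,
                dur if dur is not None else _SENTINEL,
                1.0 if dur is None else 0.0,
            ]
        return rows

    def fit_transform(self, paragraphs: Sequence[Paragraph]):
        if self.spec.text_mode == "TFIDF":
            self._tfidf = TfidfVectorizer(
                tokenizer=preprocess,
                preprocessor=_identity,
                lowercase=False,
                token_pattern=None,
                min_df=self.spec.tfidf_min_df,
                max_features=self.spec.tfidf_max_features,
            )
            X = self._tfidf.fit_transform([p.text for p in paragraphs])
            self.vocabulary_ = dict(self._tfidf.vocabulary_)
        else:
            X = sparse.csr_matrix(self._embed(paragraphs))
            self.vocabulary_ = {t: i for i, t in enumerate(sorted(self.vectors))}
        if self.spec.use_counts:
            counts = self._counts(paragraphs)
            self._scaler = StandardScaler().fit(counts)
            X = sparse.hstack([X, sparse.csr_matrix(self._scaler.transform(counts))]).tocsr()
        return X

    def transform(self, paragraphs: Sequence[Paragraph]):
        if self.spec.text_mode == "TFIDF":
            if self._tfidf is None:
                raise NotFittedError("featurizer not fitted")
            X = self._tfidf.transform([p.text for p in paragraphs])
        else:
            X = sparse.csr_matrix(self._embed(paragraphs))
        if self.spec.use_counts:
            if self._scaler is None:
                raise NotFittedError("featurizer not fitted")
            X = sparse.hstack(
                [X, sparse.csr_matrix(self._scaler.transform(self._counts(paragraphs)))]
            ).tocsr()
        return X


def featurize(
    paragraphs: Sequence[Paragraph],
    spec: FeatureSpec,
    vectors: Optional[Dict[str, np.ndarray]] = None,
    lexicon: Sequence[str] = (),
) -> Tuple[sparse.csr_matrix, ParagraphFeaturizer]:
    """Build the feature matrix and return it with the fitted featurizer."""
    featurizer = ParagraphFeaturizer(spec, vectors=vectors, lexicon=lexicon)
    X = featurizer.fit_transform(paragraphs)
    return X, featurizer


def subsample_majority(labels: Sequence[int], seed: int, ratio: float = 1.0) -> np.ndarray:
    """Random majority-class subsampling indices (1:1 balance by default).

    Keeps every minority index and a uniform random subset of majority
    indices of size ``round(ratio * n_minority)``.  Deterministic for a
    given seed; returned indices are sorted.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("subsampling requires both classes present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    n_keep = min(len(maj_idx), int(round(ratio * len(min_idx))))
    rng = np.random.default_rng(seed)
    kept = rng.choice(maj_idx, size=n_keep, replace=False)
    return np.sort(np.concatenate([min_idx, kept]))


def _make_estimator(config: TrainConfig):
    weight = "balanced" if config.imbalance == "CLASS_WEIGHTS" else None
    if config.algorithm == "LR":
        return LogisticRegression(
            C=config.lr_c, max_iter=2000, class_weight=weight, random_state=config.seed
        )
    if config.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=config.rf_trees, class_weight=weight, random_state=config.seed
        )
    # linear SVM; probabilities from a Platt sigmoid on the decision function
    return CalibratedClassifierCV(
        SVC(kernel="linear", C=config.svm_c, class_weight=weight,
            random_state=config.seed),
        method="sigmoid",
        ensemble=False,
    )


def train(X, labels: Sequence[int], config: TrainConfig):
    """Fit a classifier, applying majority subsampling when configured."""
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValueError("features and labels are misaligned")
    if config.imbalance == "SUBSAMPLE":
        idx = subsample_majority(y, config.seed, config.subsample_ratio)
        X, y = X[idx], y[idx]
    model = _make_estimator(config)
    model.fit(X, y)
    return model


def predict_proba(model, X) -> np.ndarray:
    """Positive-class probability per paragraph (raises if the model is unfitted)."""
    check_is_fitted(model)
    pos = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(X)[:, pos]


@dataclass
class CVResult:
    fold_metrics: list  # (precision, recall, f1) per fold
    mean_precision: float
    mean_recall: float
    mean_f1: float


def cross_validate(
    paragraphs: Sequence[Paragraph],
    labels: Sequence[int],
    patient_ids: Sequence[str],
    spec: FeatureSpec,
    config: TrainConfig,
    vectors: Optional[Dict[str, np.ndarray]] = None,
    lexicon: Sequence[str] = (),
    threshold: float = 0.5,
    return_proba: bool = False,
):
    """Patient-grouped k-fold cross-validation.

    Folds partition patients, so no patient contributes paragraphs to both
    the train and validation side of any fold.  The featurizer is fitted
    on each fold's training portion only.  Returns a :class:`CVResult`
    (and, optionally, out-of-fold probabilities aligned with the input).
    """
    from .evaluate import paragraph_prf  # local import avoids a cycle

    y = np.asarray(labels)
    groups = np.asarray(patient_ids)
    if len(set(groups)) < config.cv_folds:
        raise ValueError(
            f"need >= {config.cv_folds} distinct patients, got {len(set(groups))}"
        )
    splitter = GroupKFold(n_splits=config.cv_folds)
    fold_metrics = []
    oof = np.full(len(y), np.nan)
    for fold, (tr, va) in enumerate(splitter.split(np.zeros(len(y)), y, groups)):
        assert not set(groups[tr]) & set(groups[va]), "patient leakage across folds"
        featurizer = ParagraphFeaturizer(spec, vectors=vectors, lexicon=lexicon)
        Xtr = featurizer.fit_transform([paragraphs[i] for i in tr])
        Xva = featurizer.transform([paragraphs[i] for i in va])
        model = train(Xtr, y[tr], replace(config, seed=config.seed + fold))
        proba = predict_proba(model, Xva)
        oof[va] = proba
        pred = (proba >= threshold).astype(int)
        fold_metrics.append(paragraph_prf(pred, y[va]))
    means = np.mean(fold_metrics, axis=0)
    result = CVResult(fold_metrics, *map(float, means))
    return (result, oof) if return_proba else result


def save_model(path, model, featurizer: ParagraphFeaturizer, config: TrainConfig) -> None:
    """Serialise model + featurizer (with spec and vocabulary) to one file."""
    joblib.dump({"model": model, "featurizer": featurizer, "config": config}, path)


def load_model(path) -> dict:
    return joblib.load(path)
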