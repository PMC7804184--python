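"""Feature construction, imbalance handling, training and grouped CV."""

from datetime import date

import numpy as np
import pytest
from scipy import sparse

from onsetnlp import classify, segment
from onsetnlp.classify import FeatureSpec, TrainConfig
from onsetnlp.segment import Paragraph


def paras(texts):
    ps = [Paragraph("d", i, (0, 1), t) for i, t in enumerate(texts)]
    segment.attach_expressions(ps, date(2015, 6, 1))
    return ps


def test_preprocess_rules_and_idempotence():
    assert classify.preprocess("Started hearing VOICES.") == ["started", "hearing", "voices"]
    assert classify.preprocess("") == []
    for t in ["He was; unwell, in 2007!", "Weird   spacing\tand CASE"]:
        once = classify.preprocess(t)
        assert classify.preprocess(" ".join(once)) == once


def test_tfidf_min_df_excludes_rare_terms():
    texts = ["common rare"] + ["common filler"] * 5
    X, f = classify.featurize(paras(texts), FeatureSpec(tfidf_min_df=5, tfidf_max_features=10))
    assert "rare" not in f.vocabulary_
    assert "common" in f.vocabulary_
    assert X.shape[0] == len(texts)


def test_embedding_mean_matches_brute_force():
    rng = np.random.default_rng(0)
    vocab = ["alpha", "beta", "gamma", "delta"]
    vectors = {w: rng.normal(size=5) for w in vocab}
    texts = [
        " ".join(rng.choice(vocab + ["oov"], size=rng.integers(1, 8)))
        for _ in range(20)
    ] + ["oov only here"]
    ps = paras(texts)
    X, _ = classify.featurize(ps, FeatureSpec(text_mode="EMBEDDING"), vectors=vectors)
    dense = X.toarray()[:, :5]
    for i, t in enumerate(texts):
        tokens = [w for w in classify.preprocess(t) if w in vectors]
        expected = np.mean([vectors[w] for w in tokens], axis=0) if tokens else np.zeros(5)
        np.testing.assert_allclose(dense[i], expected, atol=1e-12)


def test_embedding_requires_vectors():
    with pytest.raises(ValueError):
        classify.ParagraphFeaturizer(FeatureSpec(text_mode="EMBEDDING"))


def test_count_features_appended():
    ps = paras(["He became unwell in 2007 and has been low for the past six months."])
    X, _ = classify.featurize(ps, FeatureSpec(tfidf_min_df=1, use_counts=True))
    ntext = X.shape[1] - 7
    assert ntext > 0  # 7 count columns appended after the text block


def test_subsample_exact_balance_and_determinism():
    y = np.array([1] * 10 + [0] * 100)
    idx = classify.subsample_majority(y, seed=3)
    assert len(idx) == 20
    assert (y[idx] == 1).sum() == (y[idx] == 0).sum() == 10
    assert np.array_equal(idx, classify.subsample_majority(y, seed=3))
    assert not np.array_equal(idx, classify.subsample_majority(y, seed=4))
    with pytest.raises(ValueError):
        classify.subsample_majority(np.zeros(5, dtype=int), seed=0)


def test_subsample_uniform_over_majority():
    """Each majority index is kept with frequency ~ n_min/n_maj over seeds."""
    y = np.array([1] * 10 + [0] * 100)
    hits = np.zeros(110)
    for seed in range(1000):
        hits[classify.subsample_majority(y, seed=seed)] += 1
    freqs = hits[10:] / 1000.0
    assert np.all(np.abs(freqs - 0.1) < 0.05)


def test_train_separable_and_probability_bounds():
    rng = np.random.default_rng(1)
    X = sparse.csr_matrix(np.vstack([rng.normal(3, 0.3, (20, 4)), rng.normal(-3, 0.3, (20, 4))]))
    y = np.array([1] * 20 + [0] * 20)
    for algo in ("LR", "RF", "SVM"):
        model = classify.train(X, y, TrainConfig(algorithm=algo, imbalance="NONE", seed=0))
        proba = classify.predict_proba(model, X)
        assert np.all((proba >= 0) & (proba <= 1))
        assert ((proba >= 0.5).astype(int) == y).mean() == 1.0


def test_unfitted_model_raises():
    from sklearn.exceptions import NotFittedError
    from sklearn.linear_model import LogisticRegression

    with pytest.raises(NotFittedError):
        classify.predict_proba(LogisticRegression(), sparse.eye(3).tocsr())


def test_seeded_training_reproducible():
    rng = np.random.default_rng(2)
    X = sparse.csr_matrix(rng.normal(size=(60, 8)))
    y = (rng.random(60) < 0.3).astype(int)
    cfg = TrainConfig(algorithm="RF", imbalance="SUBSAMPLE", seed=9)
    p1 = classify.predict_proba(classify.train(X, y, cfg), X)
    p2 = classify.predict_proba(classify.train(X, y, cfg), X)
    np.testing.assert_array_equal(p1, p2)


def _cv_data(n_patients=10, per_patient=6, seed=0):
    rng = np.random.default_rng(seed)
    texts, labels, pids = [], [], []
    for i in range(n_patients):
        for j in range(per_patient):
            pos = rng.random() < 0.4
            texts.append(
                "started hearing voices in 2007 first onset" if pos
                else "attended an appointment with the community team in 2014"
            )
            labels.append(int(pos))
            pids.append(f"p{i}")
    return paras(texts), np.array(labels), np.array(pids)


def test_cv_partitions_patients_without_leakage():
    ps, y, pids = _cv_data()
    spec = FeatureSpec(tfidf_min_df=1)
    result, oof = classify.cross_validate(
        ps, y, pids, spec, TrainConfig(seed=0), return_proba=True
    )
    assert not np.any(np.isnan(oof))  # every paragraph validated exactly once
    assert len(result.fold_metrics) == 5
    # trivially separable text: perfect fold metrics
    assert result.mean_precision == result.mean_recall == result.mean_f1 == 1.0


def test_cv_rejects_too_few_patients():
    ps, y, pids = _cv_data(n_patients=3)
    with pytest.raises(ValueError):
        classify.cross_validate(ps, y, pids, FeatureSpec(tfidf_min_df=1), TrainConfig(seed=0))


def test_model_roundtrip(tmp_path):
    ps, y, pids = _cv_data()
    spec = FeatureSpec(tfidf_min_df=1)
    X, f = classify.featurize(ps, spec)
    model = classify.train(X, y, TrainConfig(seed=1))
    classify.save_model(tmp_path / "m.joblib", model, f, TrainConfig(seed=1))
    loaded = classify.load_model(tmp_path / "m.joblib")
    np.testing.assert_allclose(
        classify.predict_proba(loaded["model"], loaded["featurizer"].transform(ps)),
        classify.predict_proba(model, f.transform(ps)),
    )


def test_load_word_vectors(tmp_path):
    path = tmp_path / "vecs.txt"
    path.write_text("2 3\nfoo 1.0 2.0 3.0\nbar 0.5 0.5 0.5\n")
    vecs = classify.load_word_vectors(path)
    assert set(vecs) == {"foo", "bar"}
    np.testing.assert_allclose(vecs["foo"], [1.0, 2.0, 3.0])
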