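import math

import numpy as np
import pytest

from ltcnlp import nlp_classifier as nc
from ltcnlp.seed_annotate import LabeledSet
from ltcnlp.types import UnknownIdError


def separable_corpus(n_per_class=20):
    narratives, labels = {}, {}
    for i in range(n_per_class):
        narratives[f"p{i}"] = f"ltcword alpha beta gamma item{i % 5}"
        labels[f"p{i}"] = 1
        narratives[f"n{i}"] = f"otherword alpha beta gamma item{i % 5}"
        labels[f"n{i}"] = 0
    return narratives, labels


class TestFeaturize:
    def test_identical_narratives_identical_rows(self):
        texts = {"a": "the cat sat on the mat", "b": "the cat sat on the mat",
                 "c": "a dog barked at the cat"}
        mat, _ = nc.featurize(texts, min_df=1)
        ra = mat.rows_for(["a"]).toarray()
        rb = mat.rows_for(["b"]).toarray()
        assert np.array_equal(ra, rb)

    def test_hand_computed_tfidf_three_docs(self):
        """Independent recomputation of the documented tf-idf variant
        (idf = ln((1+n)/(1+df)) + 1, counts, L2 row norm) on a toy corpus."""
        docs = {"d1": "apple banana", "d2": "apple cherry", "d3": "apple apple dates"}
        mat, _ = nc.featurize(docs, min_df=1)
        vocab = {t: j for j, t in enumerate(mat.vocabulary)}
        n = 3
        df = {"apple": 3, "banana": 1, "cherry": 1, "dates": 1,
              "apple apple": 1, "apple dates": 1}
        # doc d3 term counts: apple=2, dates=1, "apple apple"=1, "apple dates"=1
        counts = {"apple": 2, "dates": 1, "apple apple": 1, "apple dates": 1}
        raw = {
            t: c * (math.log((1 + n) / (1 + df[t])) + 1)
            for t, c in counts.items()
        }
        norm = math.sqrt(sum(v * v for v in raw.values()))
        expected = {t: v / norm for t, v in raw.items()}
        row = mat.rows_for(["d3"]).toarray()[0]
        for term, val in expected.items():
            assert row[vocab[term]] == pytest.approx(val, rel=1e-9)

    def test_term_in_every_document_gets_minimal_idf(self):
        docs = {"d1": "common alpha", "d2": "common beta", "d3": "common gamma"}
        _, feat = nc.featurize(docs, min_df=1)
        idf = feat._vectorizer.idf_
        names = list(feat._vectorizer.get_feature_names_out())
        # smoothed idf floor is exactly 1 for a term in every document
        assert idf[names.index("common")] == pytest.approx(1.0)
        assert all(v >= 1.0 for v in idf)

    def test_empty_narrative_zero_row(self):
        docs = {"a": "words here repeated words", "b": "words here too", "c": ""}
        mat, _ = nc.featurize(docs, min_df=1)
        assert mat.rows_for(["c"]).nnz == 0

    def test_transform_before_fit_errors(self):
        feat = nc.TextFeaturizer()
        with pytest.raises(RuntimeError):
            feat.transform({"a": "text"})

    def test_fit_on_empty_set_errors(self):
        with pytest.raises(ValueError):
            nc.TextFeaturizer().fit({})

    def test_transform_is_idempotent(self):
        docs = {"a": "stable text features", "b": "more stable text"}
        _, feat = nc.featurize(docs, min_df=1)
        m1 = feat.transform(docs)
        m2 = feat.transform(docs)
        assert (m1.values != m2.values).nnz == 0

    def test_oov_terms_dropped_on_transform(self):
        docs = {"a": "known tokens here", "b": "known words here"}
        _, feat = nc.featurize(docs, min_df=1)
        out = feat.transform({"x": "completely novel vocabulary"})
        assert out.values.nnz == 0


class TestTrainForest:
    def test_separable_training_accuracy(self):
        narratives, labels = separable_corpus()
        mat, _ = nc.featurize(narratives, min_df=1)
        model = nc.train_forest(mat, labels, n_trees=50, seed=0)
        probs = nc.predict_proba(model, mat)
        pred = nc.classify(probs)
        assert pred == labels

    def test_single_class_errors(self):
        narratives, _ = separable_corpus(5)
        mat, _ = nc.featurize(narratives, min_df=1)
        with pytest.raises(ValueError):
            nc.train_forest(mat, {i: 1 for i in narratives}, n_trees=5)

    def test_label_not_in_matrix_errors(self):
        narratives, labels = separable_corpus(5)
        mat, _ = nc.featurize(narratives, min_df=1)
        labels["ghost"] = 1
        with pytest.raises(UnknownIdError):
            nc.train_forest(mat, labels, n_trees=5)

    def test_same_seed_identical_predictions(self):
        narratives, labels = separable_corpus()
        mat, _ = nc.featurize(narratives, min_df=1)
        p1 = nc.predict_proba(nc.train_forest(mat, labels, 30, seed=4), mat)
        p2 = nc.predict_proba(nc.train_forest(mat, labels, 30, seed=4), mat)
        assert p1 == p2

    def test_more_trees_not_worse(self, rich_corpus):
        """Held-out F1 of a large forest >= a single tree, in expectation."""
        from ltcnlp.corpus_io import build_analytic_sample

        sample = build_analytic_sample(rich_corpus.records)
        narratives = sample.narratives()
        truth = {r.id: rich_corpus.binary_truth(r.id) for r in sample.records}
        mat, _ = nc.featurize(narratives)
        ids = sorted(narratives)
        f1_small, f1_big = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            train_ids = set(rng.choice(ids, size=len(ids) // 2, replace=False))
            test_ids = [i for i in ids if i not in train_ids]
            train = {i: truth[i] for i in train_ids}
            y_true = np.array([truth[i] for i in test_ids])
            for n_trees, sink in ((1, f1_small), (200, f1_big)):
                model = nc.train_forest(mat, train, n_trees=n_trees, seed=seed)
                probs = nc.predict_proba(model, mat)
                y_pred = np.array([int(probs[i] > 0.5) for i in test_ids])
                tp = int(((y_true == 1) & (y_pred == 1)).sum())
                fp = int(((y_true == 0) & (y_pred == 1)).sum())
                fn = int(((y_true == 1) & (y_pred == 0)).sum())
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                sink.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert np.mean(f1_big) >= np.mean(f1_small)


class TestPredictClassify:
    def test_fingerprint_mismatch_errors(self):
        narratives, labels = separable_corpus(5)
        mat, _ = nc.featurize(narratives, min_df=1)
        model = nc.train_forest(mat, labels, n_trees=5, seed=0)
        other, _ = nc.featurize({"a": "different vocabulary entirely today"},
                                min_df=1)
        with pytest.raises(ValueError):
            nc.predict_proba(model, other)

    def test_zero_row_probability_in_unit_interval_and_deterministic(self):
        narratives, labels = separable_corpus(5)
        narratives["z"] = ""
        mat, _ = nc.featurize(narratives, min_df=1)
        model = nc.train_forest(mat, labels, n_trees=20, seed=1)
        p1 = nc.predict_proba(model, mat)["z"]
        p2 = nc.predict_proba(model, mat)["z"]
        assert 0.0 <= p1 <= 1.0 and p1 == p2

    def test_probabilities_bounded(self, rich_corpus):
        narratives = {r.id: r.narrative for r in rich_corpus.records[:200]}
        labels = {r.id: rich_corpus.binary_truth(r.id)
                  for r in rich_corpus.records[:200]}
        mat, _ = nc.featurize(narratives)
        model = nc.train_forest(mat, labels, n_trees=30, seed=0)
        probs = nc.predict_proba(model, mat)
        assert all(0.0 <= p <= 1.0 for p in probs.values())

    def test_threshold_boundary_exclusive(self):
        probs = {"a": 0.50, "b": 0.51, "c": 0.0, "d": 1.0}
        assert nc.classify(probs) == {"a": 0, "b": 1, "c": 0, "d": 1}

    def test_empty_assignment(self):
        assert nc.classify({}) == {}


class TestCrossValidate:
    def test_separable_perfect_f1(self):
        narratives, labels = separable_corpus(15)
        mat, _ = nc.featurize(narratives, min_df=1)
        cv = nc.cross_validate(mat, labels, k_folds=3, seed=0, n_trees=30)
        assert cv.mean_f1 == pytest.approx(1.0)

    def test_permutation_baseline(self):
        """Shuffled balanced labels: mean F1 ~ prevalence (0.5)."""
        rng = np.random.default_rng(0)
        narratives = {f"r{i}": " ".join(
            rng.choice(["w1", "w2", "w3", "w4", "w5", "w6"], size=12)
        ) for i in range(80)}
        f1s = []
        mat, _ = nc.featurize(narratives, min_df=1)
        for seed in range(10):
            rng2 = np.random.default_rng(seed + 100)
            perm = rng2.permutation(80)
            labels = {f"r{i}": int(perm[i] < 40) for i in range(80)}
            cv = nc.cross_validate(mat, labels, k_folds=4, seed=seed, n_trees=20)
            f1s.append(cv.mean_f1)
        assert np.mean(f1s) == pytest.approx(0.5, abs=0.15)

    def test_leave_one_out_boundary(self):
        narratives, labels = separable_corpus(5)
        mat, _ = nc.featurize(narratives, min_df=1)
        cv = nc.cross_validate(mat, labels, k_folds=10, seed=0, n_trees=10)
        assert cv.n_folds == 10

    def test_too_small_class_errors(self):
        narratives, labels = separable_corpus(3)
        mat, _ = nc.featurize(narratives, min_df=1)
        with pytest.raises(ValueError):
            nc.cross_validate(mat, labels, k_folds=5, n_trees=5)

    def test_k_below_two_errors(self):
        narratives, labels = separable_corpus(5)
        mat, _ = nc.featurize(narratives, min_df=1)
        with pytest.raises(ValueError):
            nc.cross_validate(mat, labels, k_folds=1, n_trees=5)
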