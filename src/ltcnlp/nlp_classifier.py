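"""Narrative featurization and the random-forest classifier.

Featurization: lowercase, strip punctuation via word-boundary tokenization,
unigrams + bigrams, document-frequency floor of 2, smoothed tf-idf with L2
row normalization (the scikit-learn variant: ``idf = ln((1+n)/(1+df)) + 1``).
A term present in every fitted document therefore gets the minimum possible
idf of exactly 1, not 0.

The forest: each tree is trained on a bootstrap row sample with per-tree
balanced class subsampling and a sqrt-of-vocabulary feature subset at every
split.  A record's score is the forest's averaged per-tree class frequency
for the positive class; trees are grown to purity, so this is effectively
the fraction of trees voting positive.  Classification uses a strictly
greater-than threshold: a score of exactly 0.50 is negative.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.model_selection import KFold, StratifiedKFold

from .seed_annotate import LabeledSet
from .types import UnknownIdError

__all__ = [
    "FeatureMatrix",
    "TextFeaturizer",
    "ForestModel",
    "CVResult",
    "featurize",
    "train_forest",
    "predict_proba",
    "classify",
    "cross_validate",
    "DEFAULT_N_TREES",
    "DEFAULT_THRESHOLD",
]

DEFAULT_N_TREES = 1500
DEFAULT_THRESHOLD = 0.50


def _fingerprint(vocabulary: Sequence[str]) -> str:
    h = hashlib.sha256("\x00".join(vocabulary).encode("utf-8"))
    return h.hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """Sparse tf-idf matrix aligned to record ids."""

    row_ids: List[str]
    vocabulary: List[str]
    values: sparse.csr_matrix
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row count does not match id count")
        if self.values.shape[1] != len(self.vocabulary):
            raise ValueError("column count does not match vocabulary size")
        if not self.fingerprint:
            self.fingerprint = _fingerprint(self.vocabulary)
        self._index = {rid: i for i, rid in enumerate(self.row_ids)}

    def rows_for(self, ids: Sequence[str]) -> sparse.csr_matrix:
        try:
            idx = [self._index[i] for i in ids]
        except KeyError as exc:
            raise UnknownIdError(f"id not in feature matrix: {exc.args[0]!r}") from None
        return self.values[idx]

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            row_ids=list(ids),
            vocabulary=self.vocabulary,
            values=self.rows_for(ids),
            fingerprint=self.fingerprint,
        )


class TextFeaturizer:
    """Fit-once tf-idf featurizer with a frozen vocabulary after fitting."""

    def __init__(self, min_df: int = 2, ngram_range: Tuple[int, int] = (1, 2)):
        self._vectorizer = TfidfVectorizer(
            lowercase=True,
            ngram_range=ngram_range,
            min_df=min_df,
            token_pattern=r"(?u)\b\w\w+\b",
        )
        self._fitted = False

    @property
    def fitted(self) -> bool:
        return self._fitted

    @property
    def vocabulary(self) -> List[str]:
        if not self._fitted:
            raise RuntimeError("featurizer is not fitted")
        return list(self._vectorizer.get_feature_names_out())

    def fit(self, narratives: Mapping[str, str]) -> "TextFeaturizer":
        if not narratives:
            raise ValueError("cannot fit on an empty text set")
        ids = sorted(narratives)
        self._vectorizer.fit([narratives[i] for i in ids])
        self._fitted = True
        return self

    def transform(self, narratives: Mapping[str, str]) -> FeatureMatrix:
        if not self._fitted:
            raise RuntimeError("transform before fit")
        ids = sorted(narratives)
        X = self._vectorizer.transform([narratives[i] for i in ids])
        return FeatureMatrix(
            row_ids=ids, vocabulary=self.vocabulary, values=X.tocsr()
        )


def featurize(
    narratives: Mapping[str, str],
    featurizer: Optional[TextFeaturizer] = None,
    min_df: int = 2,
) -> Tuple[FeatureMatrix, TextFeaturizer]:
    """Featurize ``narratives``; fit a new featurizer unless one is given."""
    if featurizer is None:
        featurizer = TextFeaturizer(min_df=min_df).fit(narratives)
    return featurizer.transform(narratives), featurizer


@dataclass
class ForestModel:
    """A fitted random forest bound to a vocabulary fingerprint."""

    estimator: RandomForestClassifier
    vocabulary_fingerprint: str
    n_trees: int
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def _training_fingerprint(ids: Sequence[str], labels: Sequence[int]) -> str:
    payload = "\x00".join(f"{i}={l}" for i, l in zip(ids, labels))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def _make_estimator(n_trees: int, seed: Optional[int]) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )


def train_forest(
    matrix: FeatureMatrix,
    labels: LabeledSet | Mapping[str, int],
    n_trees: int = DEFAULT_N_TREES,
    seed: Optional[int] = 0,
) -> ForestModel:
    """Train the forest on the labeled rows of ``matrix``.

    Every labeled id must be present in the matrix, and both classes must be
    represented.
    """
    label_map = labels.labels() if isinstance(labels, LabeledSet) else dict(labels)
    if not label_map:
        raise ValueError("empty training set")
    ids = sorted(label_map)
    y = np.array([label_map[i] for i in ids], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    X = matrix.rows_for(ids)
    est = _make_estimator(n_trees, seed)
    est.fit(X, y)
    return ForestModel(
        estimator=est,
        vocabulary_fingerprint=matrix.fingerprint,
        n_trees=n_trees,
        training_fingerprint=_training_fingerprint(ids, y.tolist()),
    )


def predict_proba(model: ForestModel, matrix: FeatureMatrix) -> Dict[str, float]:
    """Score every row of ``matrix``; vocabulary fingerprints must match."""
    if model.vocabulary_fingerprint != matrix.fingerprint:
        raise ValueError(
            "vocabulary fingerprint mismatch between model and feature matrix"
        )
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    probs = model.estimator.predict_proba(matrix.values)[:, pos_col]
    return {rid: float(p) for rid, p in zip(matrix.row_ids, probs)}


def classify(
    probs: Mapping[str, float], threshold: float = DEFAULT_THRESHOLD
) -> Dict[str, int]:
    """Binary labels: strictly greater than ``threshold`` is positive."""
    return {rid: int(p > threshold) for rid, p in probs.items()}


@dataclass
class CVResult:
    """Per-fold precision/recall/F1 at the 0.50 threshold, plus means."""

    precision: List[float]
    recall: List[float]
    f1: List[float]

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    @property
    def n_folds(self) -> int:
        return len(self.f1)


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def cross_validate(
    matrix: FeatureMatrix,
    labels: LabeledSet | Mapping[str, int],
    k_folds: int = 5,
    seed: Optional[int] = 0,
    n_trees: int = DEFAULT_N_TREES,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVResult:
    """Stratified k-fold cross-validation of the forest at ``threshold``.

    With ``k_folds`` equal to the number of labeled items this degenerates to
    (unstratified) leave-one-out.
    """
    label_map = labels.labels() if isinstance(labels, LabeledSet) else dict(labels)
    ids = sorted(label_map)
    y = np.array([label_map[i] for i in ids], dtype=int)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes")
    X = matrix.rows_for(ids)
    if k_folds == len(ids):
        splitter = KFold(n_splits=k_folds)
        splits = splitter.split(X)
    else:
        counts = np.bincount(y)
        if counts.min() < k_folds:
            raise ValueError(
                f"smallest class has {counts.min()} items; cannot stratify into "
                f"{k_folds} folds"
            )
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)

    precision, recall, f1 = [], [], []
    for fold_i, (train_idx, test_idx) in enumerate(splits):
        est = _make_estimator(n_trees, None if seed is None else seed + fold_i)
        est.fit(X[train_idx], y[train_idx])
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        p = est.predict_proba(X[test_idx])[:, pos_col]
        pred = (p > threshold).astype(int)
        pr, rc, f = _prf(y[test_idx], pred)
        precision.append(pr)
        recall.append(rc)
        f1.append(f)
    return CVResult(precision=precision, recall=recall, f1=f1)
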