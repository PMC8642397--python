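"""Six-classifier ensemble with unanimous peptide selection.

A peak is assigned as a peptide only when all six classifiers — linear SVM,
random forest (RF), gradient-boosted trees (XGB slot), multilayer
perceptron (ANN), k-nearest neighbours (KNN) and Gaussian naive Bayes
(GNB) — vote peptide. SVM/ANN/KNN/GNB consume min-max-scaled PCA scores;
RF and the boosted trees consume the raw nine-feature vectors. The
agreement score (positive votes / 6) takes the seven values
{0, 1/6, 2/6, ..., 1} and the unanimous rule trades recall for a minimal
false-positive rate.

Hyperparameters for all members except GNB are chosen by stratified 5-fold
cross-validated accuracy over modest grids, ties broken toward the simpler
setting; all randomness derives from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._domain import AnnotatedExample, PeakFeatures, feature_matrix
from .preprocess import Preprocessor

__all__ = [
    "CLASSIFIER_KEYS",
    "PCA_ROUTED",
    "VoteRecord",
    "ConfusionCounts",
    "TrainedEnsemble",
    "default_grids",
    "stratified_split",
    "train_ensemble",
    "predict_votes",
    "evaluate_predictions",
    "diagnostics",
]

CLASSIFIER_KEYS: tuple[str, ...] = ("svm", "rf", "xgb", "ann", "knn", "gnb")
#: members that consume PCA scores; the rest consume raw features
PCA_ROUTED = frozenset({"svm", "ann", "knn", "gnb"})


def default_grids() -> dict[str, list[dict]]:
    """Default hyperparameter grids, ordered simplest-first so CV-accuracy
    ties resolve toward the simpler setting. GNB is untuned by design."""
    return {
        "svm": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0)],
        "knn": [{"n_neighbors": k} for k in (3, 5, 7, 9, 11)],
        "ann": [
            {"hidden_layer_sizes": h, "alpha": a}
            for h in ((10,), (50,), (100,), (50, 25))
            for a in (1e-4, 1e-3, 1e-2)
        ],
        "rf": [
            {"n_estimators": n, "max_depth": d}
            for n in (100, 300, 500)
            for d in (5, 10, None)
        ],
        "xgb": [
            {"n_estimators": n, "max_depth": d, "learning_rate": lr}
            for n in (100, 300)
            for d in (3, 5, 7)
            for lr in (0.05, 0.1, 0.3)
        ],
    }


def _build_classifier(key: str, params: dict, seed: int):
    if key == "svm":
        return SVC(kernel="linear", random_state=seed, **params)
    if key == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if key == "xgb":
        # gradient-boosted trees fill the XGB slot
        return GradientBoostingClassifier(random_state=seed, **params)
    if key == "ann":
        return MLPClassifier(max_iter=600, random_state=seed, **params)
    if key == "knn":
        return KNeighborsClassifier(**params)
    if key == "gnb":
        return GaussianNB(**params)
    raise ValueError(f"unknown classifier key: {key}")


@dataclass(frozen=True)
class VoteRecord:
    """Per-peak votes of the six classifiers."""

    votes: dict[str, bool]

    def __post_init__(self) -> None:
        if set(self.votes) != set(CLASSIFIER_KEYS):
            raise ValueError(f"votes must cover exactly {CLASSIFIER_KEYS}")

    @property
    def agreement(self) -> float:
        """Fraction of positive votes; one of {0, 1/6, ..., 1}."""
        return sum(self.votes.values()) / len(CLASSIFIER_KEYS)

    @property
    def unanimous_peptide(self) -> bool:
        return all(self.votes.values())


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion tallies with peptide as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision_pct(self) -> Optional[float]:
        """True peptides / predicted peptides, as a percentage rounded to one
        decimal; ``None`` (undefined) when nothing was predicted positive."""
        if self.tp + self.fp == 0:
            return None
        return round(100.0 * self.tp / (self.tp + self.fp), 1)

    @property
    def accuracy_pct(self) -> float:
        return round(100.0 * (self.tp + self.tn) / self.total, 1)


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == "peptide"


def evaluate_predictions(predictions: Sequence, annotations: Sequence) -> ConfusionCounts:
    """Tally a confusion matrix of boolean peptide predictions against
    peptide/noise annotations."""
    pred = _as_bool_labels(predictions)
    truth = _as_bool_labels(annotations)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def stratified_split(
    examples: Sequence[AnnotatedExample],
    test_fraction: Optional[float] = None,
    seed: int = 0,
    *,
    test_counts: Optional[dict[str, int]] = None,
) -> tuple[list[AnnotatedExample], list[AnnotatedExample]]:
    """Split examples into train/test preserving class balance.

    Either ``test_fraction`` (proportional stratification, within rounding)
    or explicit per-class ``test_counts`` (e.g. ``{"peptide": 161, "noise":
    158}`` to replicate a published split whose class counts are not exactly
    proportional). Deterministic for a fixed seed.
    """
    labels = {ex.annotation for ex in examples}
    if labels != {"peptide", "noise"}:
        raise ValueError(f"both classes must be present, got {sorted(labels)}")
    if test_counts is None:
        if test_fraction is None or not (0.0 < test_fraction < 1.0):
            raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    train: list[AnnotatedExample] = []
    test: list[AnnotatedExample] = []
    for label in ("peptide", "noise"):
        members = [ex for ex in examples if ex.annotation == label]
        order = rng.permutation(len(members))
        if test_counts is not None:
            n_test = int(test_counts[label])
            if not (0 <= n_test <= len(members)):
                raise ValueError(f"test count {n_test} out of range for class {label}")
        else:
            n_test = int(round(test_fraction * len(members)))
            n_test = min(max(n_test, 1), len(members) - 1)
        test.extend(members[i] for i in order[:n_test])
        train.extend(members[i] for i in order[n_test:])
    return train, test


@dataclass
class TrainedEnsemble:
    """Preprocessing state plus the six fitted classifiers."""

    preprocessor: Preprocessor
    classifiers: dict = field(repr=False)
    hyperparameters: dict[str, dict] = field(default_factory=dict)
    cv_accuracy: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.classifiers) != set(CLASSIFIER_KEYS):
            raise ValueError(f"ensemble must contain exactly {CLASSIFIER_KEYS}")

    @property
    def routing(self) -> dict[str, str]:
        return {k: ("pca" if k in PCA_ROUTED else "raw") for k in CLASSIFIER_KEYS}

    def _vote_matrix(self, X: np.ndarray) -> dict[str, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.preprocessor.feature_min.size:
            raise ValueError(
                f"expected {self.preprocessor.feature_min.size} features, got {X.shape}"
            )
        X_pca = self.preprocessor.transform(X)
        out = {}
        for key, clf in self.classifiers.items():
            inputs = X_pca if key in PCA_ROUTED else X
            out[key] = clf.predict(inputs).astype(bool)
        return out

    def predict_votes_batch(self, X: np.ndarray) -> list[VoteRecord]:
        """VoteRecords for each row of a raw feature matrix."""
        votes = self._vote_matrix(X)
        n = len(next(iter(votes.values())))
        return [
            VoteRecord(votes={k: bool(votes[k][i]) for k in CLASSIFIER_KEYS})
            for i in range(n)
        ]

    def predict_votes(self, features: PeakFeatures | np.ndarray) -> VoteRecord:
        row = features.to_array() if isinstance(features, PeakFeatures) else np.asarray(features)
        return self.predict_votes_batch(row.reshape(1, -1))[0]


def _cv_accuracy(model, X: np.ndarray, y: np.ndarray, cv: StratifiedKFold) -> float:
    scores = []
    for tr_idx, te_idx in cv.split(X, y):
        fitted = clone(model).fit(X[tr_idx], y[tr_idx])
        scores.append(np.mean(fitted.predict(X[te_idx]) == y[te_idx]))
    return float(np.mean(scores))


def train_ensemble(
    train: Sequence[AnnotatedExample],
    seed: int = 0,
    grids: Optional[dict[str, list[dict]]] = None,
    *,
    variance_target: float = 0.99,
    n_components: Optional[int] = None,
) -> TrainedEnsemble:
    """Fit the preprocessing and all six classifiers on a training set.

    Grid members for svm/rf/xgb/ann/knn are scored by stratified 5-fold CV
    accuracy (first grid entry wins ties, grids are ordered simplest-first);
    GNB is fitted directly without tuning. The winning configuration is
    refitted on the full training set.
    """
    X, y_lab = feature_matrix(train)
    y = _as_bool_labels(y_lab)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both peptide and noise examples")

    grids = dict(default_grids() if grids is None else grids)
    seeds = np.random.SeedSequence(seed).generate_state(len(CLASSIFIER_KEYS) + 1) % (2**31)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(seeds[-1]))

    pre = Preprocessor.fit(X, variance_target=variance_target, n_components=n_components)
    X_pca = pre.transform(X)

    classifiers: dict = {}
    chosen: dict[str, dict] = {}
    cv_acc: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, key in enumerate(CLASSIFIER_KEYS):
            inputs = X_pca if key in PCA_ROUTED else X
            clf_seed = int(seeds[i])
            if key == "gnb":
                classifiers[key] = _build_classifier(key, {}, clf_seed).fit(inputs, y)
                cv_acc[key] = _cv_accuracy(_build_classifier(key, {}, clf_seed), inputs, y, cv)
                continue
            grid = grids.get(key)
            if not grid:
                raise ValueError(f"empty hyperparameter grid for tuned classifier {key!r}")
            best_params, best_score = None, -np.inf
            for params in grid:
                score = _cv_accuracy(_build_classifier(key, params, clf_seed), inputs, y, cv)
                if score > best_score:  # strict: first (simplest) entry wins ties
                    best_params, best_score = params, score
            classifiers[key] = _build_classifier(key, best_params, clf_seed).fit(inputs, y)
            chosen[key] = dict(best_params)
            cv_acc[key] = best_score

    return TrainedEnsemble(
        preprocessor=pre,
        classifiers=classifiers,
        hyperparameters=chosen,
        cv_accuracy=cv_acc,
        seed=seed,
    )


def predict_votes(model: TrainedEnsemble, features: PeakFeatures | np.ndarray) -> VoteRecord:
    """Six-way votes for one peak (see :meth:`TrainedEnsemble.predict_votes`)."""
    return model.predict_votes(features)


def _diagnostic_pipeline(key: str, seed: int):
    """A fold-safe pipeline (scaling+PCA refit per fold for PCA-routed members)
    using the simplest default configuration of the given classifier."""
    from sklearn.decomposition import PCA
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import MinMaxScaler

    params = default_grids().get(key, [{}])[0]
    clf = _build_classifier(key, params, seed)
    if key in PCA_ROUTED:
        return Pipeline(
            [
                ("minmax", MinMaxScaler(clip=True)),
                ("pca", PCA(n_components=0.99, svd_solver="full")),
                ("clf", clf),
            ]
        )
    return Pipeline([("clf", clf)])


def diagnostics(
    examples: Sequence[AnnotatedExample],
    seed: int = 0,
    n_permutations: int = 30,
    curve_sizes: Optional[Sequence[int]] = None,
    classifiers: Sequence[str] = CLASSIFIER_KEYS,
) -> dict:
    """Learning curves and a label-permutation test for overfitting checks.

    Returns ``{"learning_curve": DataFrame, "permutation": {key: {...}}}``.
    The curve reports training and cross-validated accuracy at increasing
    training sizes; the permutation arm reports the CV accuracy distribution
    under shuffled labels and the empirical p-value of the unshuffled score.
    """
    import pandas as pd
    from sklearn.model_selection import learning_curve as sk_learning_curve
    from sklearn.model_selection import permutation_test_score

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X, y_lab = feature_matrix(examples)
    y = _as_bool_labels(y_lab)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % (2**31))
    max_train = len(y) - int(np.ceil(len(y) / 5))
    if curve_sizes is None:
        curve_sizes = np.unique(np.linspace(20, max_train, 5).astype(int))
    elif max(curve_sizes) > max_train:
        raise ValueError(
            f"curve size {max(curve_sizes)} exceeds the {max_train} examples "
            "available for training under 5-fold CV"
        )

    rows = []
    permutation: dict[str, dict] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for key in classifiers:
            pipe = _diagnostic_pipeline(key, seed % (2**31))
            sizes, train_scores, cv_scores = sk_learning_curve(
                pipe, X, y, train_sizes=np.asarray(curve_sizes), cv=cv, shuffle=False
            )
            for s, tr, te in zip(sizes, train_scores.mean(axis=1), cv_scores.mean(axis=1)):
                rows.append(
                    {"classifier": key, "train_size": int(s),
                     "train_accuracy": float(tr), "cv_accuracy": float(te)}
                )
            score, perm_scores, pvalue = permutation_test_score(
                pipe, X, y, cv=cv, n_permutations=n_permutations,
                random_state=seed % (2**31), scoring="accuracy",
            )
            permutation[key] = {
                "observed_accuracy": float(score),
                "permuted_accuracies": np.asarray(perm_scores, dtype=float),
                "p_value": float(pvalue),
            }
    return {"learning_curve": pd.DataFrame(rows), "permutation": permutation}
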