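"""20-classifier comparison harness under repeated stratified cross-validation.

The zoo mirrors the presets of the interactive classification-learner tool
family: three decision trees (fine/medium/coarse), two discriminant models
(LDA/QDA), six SVMs (linear, quadratic, cubic, fine/medium/coarse Gaussian),
four KNNs (fine/medium/coarse/weighted) and five ensembles (subspace
discriminant, subspace KNN, AdaBoost trees, bagged trees, RUSBoost trees).
Hyperparameters are pinned, overridable via ``build_model_zoo`` arguments.

Evaluation: stratified 5-fold cross-validation repeated for 10 rounds with a
round-specific seed; per round the accuracy is pooled correct/total over the
five test folds; the headline number per model is the mean over rounds.
Features are standardized inside each training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger("seqradiomics")

MODEL_FAMILIES = {
    "fine_tree": "tree", "medium_tree": "tree", "coarse_tree": "tree",
    "lda": "discriminant", "qda": "discriminant",
    "svm_linear": "svm", "svm_quadratic": "svm", "svm_cubic": "svm",
    "svm_fine_gaussian": "svm", "svm_medium_gaussian": "svm",
    "svm_coarse_gaussian": "svm",
    "knn_fine": "knn", "knn_medium": "knn", "knn_coarse": "knn",
    "knn_weighted": "knn",
    "ens_subspace_discriminant": "ensemble", "ens_subspace_knn": "ensemble",
    "ens_adaboost_tree": "ensemble", "ens_bagged_tree": "ensemble",
    "ens_rusboost_tree": "ensemble",
}

MODEL_NAMES = tuple(MODEL_FAMILIES)


class CappedKNN(ClassifierMixin, BaseEstimator):
    """KNN whose neighbor count is capped at n_train - 1 at fit time."""

    def __init__(self, n_neighbors: int = 10, weights="uniform"):
        self.n_neighbors = n_neighbors
        self.weights = weights

    def fit(self, X, y):
        k = min(self.n_neighbors, len(y) - 1)
        if k < self.n_neighbors:
            log.debug("knn: capping k at %d (n_train=%d)", k, len(y))
        self._knn = KNeighborsClassifier(n_neighbors=max(1, k),
                                         weights=self.weights)
        self._knn.fit(X, y)
        self.classes_ = self._knn.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "_knn")
        return self._knn.predict(X)


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """Boosting with per-iteration random undersampling (SAMME updates).

    Each round draws a class-balanced subsample (every class down to the
    minority-class count, sampling probabilities proportional to the current
    boosting weights), fits the base tree on it, then applies standard SAMME
    weight updates evaluated on the full training set.
    """

    def __init__(self, estimator=None, n_estimators: int = 30,
                 learning_rate: float = 0.1, random_state: int | None = None):
        self.estimator = estimator
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, yi = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        n = len(yi)
        rng = np.random.default_rng(self.random_state)
        base = self.estimator or DecisionTreeClassifier(max_leaf_nodes=21)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        n_min = np.bincount(yi).min()
        for _ in range(self.n_estimators):
            idx = []
            for c in range(k):
                members = np.flatnonzero(yi == c)
                pw = w[members] / w[members].sum()
                take = min(n_min, len(members))
                idx.append(rng.choice(members, size=take, replace=False, p=pw)
                           if take < len(members) else members)
            idx = np.concatenate(idx)
            est = clone(base)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(2 ** 31)))
            est.fit(X[idx], yi[idx])
            pred = est.predict(X)
            err = float(w[pred != yi].sum() / w.sum())
            if err >= 1.0 - 1.0 / k:  # no better than chance: skip round
                continue
            err = max(err, 1e-10)
            alpha = self.learning_rate * (np.log((1 - err) / err) + np.log(k - 1))
            w = w * np.exp(alpha * (pred != yi))
            w = w / w.sum()
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            if err <= 1e-10:
                break
        if not self.estimators_:  # fall back to one unweighted tree
            est = clone(base)
            est.fit(X, yi)
            self.estimators_, self.alphas_ = [est], [1.0]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)))
        for est, alpha in zip(self.estimators_, self.alphas_):
            votes[np.arange(len(X)), est.predict(X)] += alpha
        return self.classes_[votes.argmax(axis=1)]


def build_model_zoo(task: str = "four_class", n_features: int | None = None,
                    seed: int = 0, n_ensemble: int = 30) -> dict:
    """The 20 pinned classifier presets, each wrapped with a fold-local
    standardizer. ``n_features`` sets the Gaussian kernel scales and the
    subspace dimension (resolved at fit time from the data when None via a
    conservative default of 20)."""
    p = n_features or 20
    sqrt_p = float(np.sqrt(p))
    subspace = max(1, int(np.ceil(p / 2)))
    boost_tree = DecisionTreeClassifier(max_leaf_nodes=21, random_state=seed)
    zoo = {
        "fine_tree": DecisionTreeClassifier(max_leaf_nodes=101, criterion="gini",
                                            random_state=seed),
        "medium_tree": DecisionTreeClassifier(max_leaf_nodes=21, criterion="gini",
                                              random_state=seed),
        "coarse_tree": DecisionTreeClassifier(max_leaf_nodes=5, criterion="gini",
                                              random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
        "qda": QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "svm_linear": SVC(kernel="linear", C=1.0, random_state=seed),
        "svm_quadratic": SVC(kernel="poly", degree=2, coef0=1.0, C=1.0,
                             gamma="scale", random_state=seed),
        "svm_cubic": SVC(kernel="poly", degree=3, coef0=1.0, C=1.0,
                         gamma="scale", random_state=seed),
        "svm_fine_gaussian": SVC(kernel="rbf", C=1.0,
                                 gamma=1.0 / (sqrt_p / 4) ** 2, random_state=seed),
        "svm_medium_gaussian": SVC(kernel="rbf", C=1.0,
                                   gamma=1.0 / sqrt_p ** 2, random_state=seed),
        "svm_coarse_gaussian": SVC(kernel="rbf", C=1.0,
                                   gamma=1.0 / (4 * sqrt_p) ** 2,
                                   random_state=seed),
        "knn_fine": CappedKNN(n_neighbors=1),
        "knn_medium": CappedKNN(n_neighbors=10),
        "knn_coarse": CappedKNN(n_neighbors=100),
        "knn_weighted": CappedKNN(n_neighbors=10, weights=_squared_inverse),
        "ens_subspace_discriminant": BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(), n_estimators=n_ensemble,
            max_features=subspace, bootstrap=False, bootstrap_features=False,
            random_state=seed),
        "ens_subspace_knn": BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=n_ensemble, max_features=subspace, bootstrap=False,
            bootstrap_features=False, random_state=seed),
        "ens_adaboost_tree": AdaBoostClassifier(
            estimator=clone(boost_tree), n_estimators=n_ensemble,
            learning_rate=0.1, random_state=seed),
        "ens_bagged_tree": BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=n_ensemble, random_state=seed),
        "ens_rusboost_tree": RUSBoostClassifier(
            estimator=clone(boost_tree), n_estimators=n_ensemble,
            learning_rate=0.1, random_state=seed),
    }
    assert tuple(zoo) == MODEL_NAMES
    return {name: Pipeline([("scale", StandardScaler()), ("clf", model)])
            for name, model in zoo.items()}


@dataclass
class CVPlan:
    folds: int = 5
    rounds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class ModelReport:
    """Per-model accuracies of one repeated-CV comparison."""

    mean_accuracy: dict  # model -> mean over rounds
    round_accuracies: dict  # model -> list of per-round pooled accuracies
    confusion: dict  # model -> summed confusion matrix of the last round
    classes: list = field(default_factory=list)
    plan: CVPlan = field(default_factory=CVPlan)

    def to_table(self) -> str:
        """Text table shaped like a model-performance comparison table."""
        width = max(len(n) for n in self.mean_accuracy)
        lines = [f"{'Model':<{width}}  Accuracy (%)"]
        for name, acc in self.mean_accuracy.items():
            lines.append(f"{name:<{width}}  {100 * acc:11.1f}")
        return "\n".join(lines)


def repeated_cv_accuracy(X: np.ndarray, y: np.ndarray, zoo: dict | None = None,
                         plan: CVPlan | None = None,
                         selector=None) -> ModelReport:
    """Evaluate every zoo model under repeated stratified k-fold CV.

    When ``selector`` is given (an unfitted transformer such as
    :class:`~seqradiomics.selection.TwoStageSelector`), it is cloned and
    re-fitted inside every training fold (nested selection), so the reported
    accuracy is free of selection leakage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan = plan or CVPlan()
    classes = np.unique(y)
    if np.bincount(np.searchsorted(classes, y)).min() < plan.folds:
        raise ValueError("every class needs at least `folds` members")
    if zoo is None:
        n_feat = X.shape[1]
        if selector is not None:  # models see the selector's output width
            n_feat = getattr(selector, "final_count", None) or min(20, n_feat)
        zoo = build_model_zoo(n_features=n_feat, seed=plan.seed)
    rounds = {name: [] for name in zoo}
    confusion = {}
    for r in range(plan.rounds):
        skf = StratifiedKFold(n_splits=plan.folds, shuffle=True,
                              random_state=plan.seed + r)
        pred = {name: np.empty(len(y), dtype=object) for name in zoo}
        for train, test in skf.split(X, y):
            Xtr, Xte = X[train], X[test]
            if selector is not None:
                sel = clone(selector)
                sel.fit(Xtr, y[train])
                Xtr, Xte = sel.transform(Xtr), sel.transform(Xte)
            for name, model in zoo.items():
                m = clone(model)
                m.fit(Xtr, y[train])
                pred[name][test] = m.predict(Xte)
        for name in zoo:
            rounds[name].append(float((pred[name] == y).mean()))
            if r == plan.rounds - 1:
                confusion[name] = confusion_matrix(
                    y, pred[name].astype(classes.dtype), labels=classes)
    return ModelReport(
        mean_accuracy={n: float(np.mean(a)) for n, a in rounds.items()},
        round_accuracies=rounds,
        confusion=confusion,
        classes=list(classes),
        plan=plan,
    )


def best_model(report: ModelReport) -> tuple[list[str], float]:
    """All models tied at the maximum mean accuracy, and that accuracy."""
    if not report.mean_accuracy:
        raise ValueError("empty report")
    top = max(report.mean_accuracy.values())
    names = [n for n, a in report.mean_accuracy.items()
             if abs(a - top) < 1e-12]
    return names, float(top)
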