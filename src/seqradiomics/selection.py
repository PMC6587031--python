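"""Two-stage feature selection and the Rad-score.

Stage 1 (coarse) places every feature in a 2D plane of (hypothesis-test
p-value, single-feature cross-validated error) and keeps the features inside
an elliptical acceptance domain::

    (p / a)^2 + (e / b)^2 < 1          (strict; the boundary is rejected)

with acceptance factors a, b either fixed per task — (0.6, 0.85) for the
four-subtype task, (0.54, 0.76) for TN vs non-TN — or tuned by an exhaustive
0.01-step grid search to retain a target fraction (about half) of the
catalog. The p-value is one-way ANOVA for the four-class task and a pooled
two-sample t-test for the binary task; the CV error is that of a univariate
linear-discriminant classifier under stratified k-fold.

Stage 2 (fine) ranks the accepted features with three regularized linear
models (lasso, ridge, elastic net with mixing 0.5; logistic loss, penalty
strength chosen by internal stratified 5-fold CV), sums the three ranks into
a fused score, keeps the ``top_k`` lowest scores, and greedily removes
features whose absolute Pearson correlation with an already-kept feature
exceeds the threshold (default 0.4), stopping at the configured final count.

The Rad-score is a per-subject linear combination of the final standardized
features: the logistic linear predictor for the binary task, the first
linear-discriminant axis for the four-class task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

log = logging.getLogger("seqradiomics")

RANKING_METHODS = ("lasso", "ridge", "elastic_net")

_C_GRID = np.logspace(-2, 2, 5)


# ---------------------------------------------------------------------------
# Coarse stage
# ---------------------------------------------------------------------------

def per_feature_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column p-value: pooled t-test (2 classes) or one-way ANOVA (>2).

    A column that is constant within every group (zero between- and
    within-group variance) gets p = 1 by convention.
    """
    X = np.asarray(X, dtype=float)
    classes = np.unique(y)
    groups = [X[y == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    with np.errstate(divide="ignore", invalid="ignore"):
        if len(classes) == 2:
            p = sps.ttest_ind(groups[0], groups[1], axis=0, equal_var=True).pvalue
        else:
            p = sps.f_oneway(*groups, axis=0).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        log.warning("p-value: %d degenerate columns set to 1", int(degenerate.sum()))
        p[degenerate] = 1.0
    return np.clip(p, 0.0, 1.0)


def per_feature_cv_errors(X: np.ndarray, y: np.ndarray, folds: int = 5,
                          seed: int = 0) -> np.ndarray:
    """Stratified k-fold error of a univariate linear-discriminant classifier,
    computed for every column at once.

    The classifier is Gaussian LDA in one dimension: class means, pooled
    within-class variance (denominator n - K) and log class priors estimated
    on the training folds; prediction is the class maximizing the linear
    discriminant. Errors are pooled over folds (misclassified / N).
    """
    X = np.asarray(X, dtype=float)
    classes, yi = np.unique(y, return_inverse=True)
    k = len(classes)
    n, p = X.shape
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    wrong = np.zeros(p)
    for train, test in skf.split(X, yi):
        counts = np.bincount(yi[train], minlength=k)
        if counts.min() < 1:
            raise ValueError("a class is absent from a training fold")
        mu = np.stack([X[train][yi[train] == c].mean(axis=0) for c in range(k)])
        ss = np.zeros(p)
        for c in range(k):
            d = X[train][yi[train] == c] - mu[c]
            ss += (d ** 2).sum(axis=0)
        var = ss / max(1, len(train) - k)
        var = np.where(var > 0, var, 1e-12)
        log_prior = np.log(counts / len(train))
        # discriminant for class c: x * mu_c / var - mu_c^2 / (2 var) + log pi_c
        scores = np.stack([
            X[test] * (mu[c] / var) - (mu[c] ** 2) / (2 * var) + log_prior[c]
            for c in range(k)
        ])  # (k, n_test, p)
        pred = scores.argmax(axis=0)
        wrong += (pred != yi[test][:, None]).sum(axis=0)
    return wrong / n


def per_feature_cv_error(column: np.ndarray, y: np.ndarray, folds: int = 5,
                         seed: int = 0) -> float:
    return float(per_feature_cv_errors(
        np.asarray(column, dtype=float).reshape(-1, 1), y, folds, seed)[0])


def ellipse_accept(p_value, cv_error, a: float, b: float):
    """Strict elliptical acceptance: (p/a)^2 + (e/b)^2 < 1."""
    p_value = np.asarray(p_value, dtype=float)
    cv_error = np.asarray(cv_error, dtype=float)
    inside = (p_value / a) ** 2 + (cv_error / b) ** 2 < 1.0
    return bool(inside) if inside.ndim == 0 else inside


def tune_acceptance_factors(p_values: np.ndarray, cv_errors: np.ndarray,
                            target_fraction: float = 0.5) -> tuple[float, float]:
    """Exhaustive 0.01-step grid search for (a, b).

    Minimizes |retained - target_fraction * P|; ties are broken by smaller
    ellipse area a*b, then by smaller a.
    """
    p2 = np.asarray(p_values, dtype=float) ** 2
    e2 = np.asarray(cv_errors, dtype=float) ** 2
    grid = np.round(np.arange(1, 101) * 0.01, 2)
    target = target_fraction * p2.size
    best = None  # (|diff|, a*b, a, b)
    b2 = grid ** 2
    for a in grid:
        t = p2 / a ** 2  # (P,)
        retained = ((t[None, :] + e2[None, :] / b2[:, None]) < 1.0).sum(axis=1)
        diffs = np.abs(retained - target)
        for bi, diff in enumerate(diffs):
            key = (diff, a * grid[bi], a)
            if best is None or key < best[0]:
                best = (key, (float(a), float(grid[bi])))
    return best[1]


# ---------------------------------------------------------------------------
# Fine stage
# ---------------------------------------------------------------------------

def _cv_best_c(X: np.ndarray, yi: np.ndarray, make_model, folds: int,
               seed: int) -> float:
    folds = min(folds, int(np.bincount(yi).min()))
    if folds < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, yi))
    best_c, best_dev = _C_GRID[0], np.inf
    for c in _C_GRID:
        dev = 0.0
        for train, test in splits:
            model = make_model(c)
            model.fit(X[train], yi[train])
            prob = np.clip(model.predict_proba(X[test]), 1e-12, 1.0)
            dev += -np.log(prob[np.arange(len(test)), yi[test]]).mean()
        dev /= len(splits)
        if dev < best_dev - 1e-12:
            best_dev, best_c = dev, c
    return float(best_c)


def regularized_rankings(X: np.ndarray, y: np.ndarray, folds: int = 5,
                         seed: int = 0, l1_ratio: float = 0.5) -> np.ndarray:
    """Per-feature ranks (1 = most important) from lasso / ridge / elastic net.

    ``X`` must be standardized. Importance is the magnitude of the
    standardized coefficient (summed |coef| across classes for multinomial
    models); tied importances share the mean rank. Returns a (3, P) array
    ordered like :data:`RANKING_METHODS`.
    """
    X, y = check_X_y(X, y, dtype=float)
    _, yi = np.unique(y, return_inverse=True)
    if X.shape[0] < 10:
        raise ValueError("fine-stage ranking needs at least 10 subjects")

    def factory(solver, ratio):
        def make(c):
            return LogisticRegression(l1_ratio=ratio, C=c, solver=solver,
                                      max_iter=500, tol=1e-3,
                                      random_state=seed)
        return make

    # l1_ratio 1 = lasso, 0 = ridge, 0.5 = elastic net
    factories = [
        factory("saga", 1.0),
        factory("lbfgs", 0.0),
        factory("saga", l1_ratio),
    ]
    ranks = np.empty((3, X.shape[1]))
    for m, make in enumerate(factories):
        c = _cv_best_c(X, yi, make, folds, seed)
        model = make(c)
        model.fit(X, yi)
        importance = np.abs(model.coef_).sum(axis=0)
        ranks[m] = sps.rankdata(-importance, method="average")
    return ranks


def rank_fusion(ranks: np.ndarray) -> np.ndarray:
    """Sum the per-method ranks into one fused score (lower is better)."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 2:
        raise ValueError("expected a (n_methods, P) rank array")
    return ranks.sum(axis=0)


def correlation_prune(X: np.ndarray, ordered_indices: np.ndarray,
                      threshold: float = 0.4,
                      final_count: int | None = None) -> list[int]:
    """Greedy scan in score order keeping features uncorrelated with the kept.

    A candidate is kept iff its absolute Pearson correlation with every
    already-kept feature is <= ``threshold``; the scan stops once
    ``final_count`` features are kept (may return fewer).
    """
    kept: list[int] = []
    X = np.asarray(X, dtype=float)
    for j in ordered_indices:
        ok = True
        for k in kept:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if np.isfinite(r) and abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(int(j))
            if final_count is not None and len(kept) >= final_count:
                break
    if final_count is not None and len(kept) < final_count:
        log.warning("correlation pruning kept only %d of %d requested features",
                    len(kept), final_count)
    return kept


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Audit record of one two-stage selection run."""

    acceptance_factors: tuple[float, float]
    coarse_accepted: list[int]
    p_values: np.ndarray
    cv_errors: np.ndarray
    method_ranks: dict = field(default_factory=dict)  # method -> ranks (accepted set)
    fused_scores: np.ndarray | None = None
    top_k: list[int] = field(default_factory=list)
    final: list[int] = field(default_factory=list)
    column_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        name = lambda j: self.column_ids[j] if self.column_ids else int(j)
        return {
            "acceptance_factors": list(self.acceptance_factors),
            "n_coarse_accepted": len(self.coarse_accepted),
            "coarse_accepted": [name(j) for j in self.coarse_accepted],
            "top_k": [name(j) for j in self.top_k],
            "final": [name(j) for j in self.final],
        }


class TwoStageSelector(TransformerMixin, BaseEstimator):
    """Coarse elliptical gate + rank-fusion fine selection, as a transformer.

    Parameters
    ----------
    task : {"auto", "four_class", "tn_binary"}
        Decides the per-task defaults for acceptance factors and final
        count; "auto" infers binary vs multiclass from the labels.
    acceptance_factors : (a, b) or None
        Ellipse semi-axes; None uses the per-task default.
    auto_tune : bool
        Grid-search (a, b) to retain ``tune_target_fraction`` of the catalog
        instead of using fixed factors.
    top_k : int
        Number of lowest fused scores carried into correlation pruning.
    corr_threshold : float
        Maximum allowed pairwise |Pearson r| among final features.
    final_count : int or None
        Final feature-set size; None uses 20 (four-class) / 8 (binary).
    cv_folds, seed
        Stratified-CV geometry and random seed for both stages.

    Attributes (after fit)
    ----------------------
    support_ : boolean mask of the final features over all input columns.
    result_ : :class:`SelectionResult` audit record.
    """

    def __init__(self, task: str = "auto",
                 acceptance_factors: tuple[float, float] | None = None,
                 auto_tune: bool = False, tune_target_fraction: float = 0.5,
                 top_k: int = 40, corr_threshold: float = 0.4,
                 final_count: int | None = None, cv_folds: int = 5,
                 seed: int = 0):
        self.task = task
        self.acceptance_factors = acceptance_factors
        self.auto_tune = auto_tune
        self.tune_target_fraction = tune_target_fraction
        self.top_k = top_k
        self.corr_threshold = corr_threshold
        self.final_count = final_count
        self.cv_folds = cv_folds
        self.seed = seed

    def _resolve(self, n_classes: int) -> tuple[tuple[float, float], int]:
        from seqradiomics.config import (DEFAULT_ACCEPTANCE_FACTORS,
                                         DEFAULT_FINAL_COUNT)
        task = self.task
        if task == "auto":
            task = "tn_binary" if n_classes == 2 else "four_class"
        factors = self.acceptance_factors or DEFAULT_ACCEPTANCE_FACTORS[task]
        final = self.final_count or DEFAULT_FINAL_COUNT[task]
        return tuple(factors), final

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        n, p = X.shape
        classes = np.unique(y)
        factors, final_count = self._resolve(len(classes))

        p_values = per_feature_pvalues(X, y)
        cv_errors = per_feature_cv_errors(X, y, self.cv_folds, self.seed)
        if self.auto_tune:
            factors = tune_acceptance_factors(p_values, cv_errors,
                                              self.tune_target_fraction)
        accept = ellipse_accept(p_values, cv_errors, *factors)
        accepted = np.flatnonzero(accept)
        if accepted.size == 0:
            log.warning("elliptical gate accepted no features; keeping all")
            accepted = np.arange(p)

        Xa = X[:, accepted]
        mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
        Xs = (Xa - mu) / np.where(sd > 0, sd, 1.0)
        ranks = regularized_rankings(Xs, y, folds=self.cv_folds, seed=self.seed)
        fused = rank_fusion(ranks)
        order = np.argsort(fused, kind="stable")
        top = order[: self.top_k]
        final_local = correlation_prune(Xa, top, self.corr_threshold, final_count)

        self.acceptance_factors_ = factors
        self.p_values_ = p_values
        self.cv_errors_ = cv_errors
        self.coarse_accepted_ = accepted
        self.ranks_ = ranks
        self.fused_scores_ = fused
        self.top_k_idx_ = accepted[top]
        self.final_idx_ = accepted[np.asarray(final_local, dtype=int)]
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.final_idx_] = True
        self.n_features_in_ = p
        self.result_ = SelectionResult(
            acceptance_factors=factors,
            coarse_accepted=[int(j) for j in accepted],
            p_values=p_values,
            cv_errors=cv_errors,
            method_ranks={m: ranks[i] for i, m in enumerate(RANKING_METHODS)},
            fused_scores=fused,
            top_k=[int(j) for j in self.top_k_idx_],
            final=[int(j) for j in self.final_idx_],
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.flatnonzero(self.support_) if indices else self.support_


class RadScoreModel(TransformerMixin, BaseEstimator):
    """Per-subject Rad-score: a coefficient-weighted linear combination of the
    (standardized) selected features.

    Binary task: logistic regression; the Rad-score is the linear predictor.
    Four-class task: the first linear-discriminant axis. Fitted attributes
    expose ``coefficients_`` (one per feature, standardized space) and
    ``intercept_``.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        self.classes_, yi = np.unique(y, return_inverse=True)
        if len(self.classes_) == 2:
            # the TN (triple-negative) class is the positive one when present
            pos = "TN" if "TN" in self.classes_ else self.classes_[1]
            self.positive_class_ = pos
            model = LogisticRegression(C=1e6, max_iter=2000,
                                       random_state=self.seed)
            model.fit(Xs, (np.asarray(y) == pos).astype(int))
            self.coefficients_ = model.coef_[0].copy()
            self.intercept_ = float(model.intercept_[0])
        else:
            lda = LinearDiscriminantAnalysis()
            lda.fit(Xs, yi)
            axis = lda.scalings_[:, 0]
            self.coefficients_ = axis.copy()
            self.intercept_ = float(-(lda.xbar_ @ axis))
        self._model = None
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coefficients_")
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Xs @ self.coefficients_ + self.intercept_

    def transform(self, X):
        return self.decision_function(X).reshape(-1, 1)


# ---------------------------------------------------------------------------
# Functional wrapper over the estimator surface
# ---------------------------------------------------------------------------

def task_labels(labels, task: str) -> np.ndarray:
    """Map subtype labels to task targets (binary collapses to TN / nonTN)."""
    labels = np.asarray(labels)
    if task == "tn_binary":
        return np.where(labels == "TN", "TN", "nonTN")
    return labels


def two_stage_select(table, config) -> tuple[TwoStageSelector, SelectionResult]:
    """Run the two-stage selection on a feature table under a pipeline config."""
    y = task_labels(table.labels, config.task)
    selector = TwoStageSelector(
        task=config.task,
        acceptance_factors=None if config.auto_tune_factors
        else config.acceptance_factors,
        auto_tune=config.auto_tune_factors,
        top_k=config.fine_top_k,
        corr_threshold=config.corr_threshold,
        final_count=config.final_feature_count,
        cv_folds=config.cv_folds,
        seed=config.seed,
    )
    selector.fit(table.values, y)
    selector.result_.column_ids = table.column_ids
    return selector, selector.result_
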