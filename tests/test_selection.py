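"""Two-stage selection: coarse gate statistics, elliptical acceptance and its
tuning, rank fusion, correlation pruning, the composed selector, and the
Rad-score."""

import numpy as np
import pytest
from scipy import stats as sps

from seqradiomics.config import PipelineConfig
from seqradiomics.selection import (RadScoreModel, TwoStageSelector,
                                    correlation_prune, ellipse_accept,
                                    per_feature_cv_error,
                                    per_feature_cv_errors, per_feature_pvalues,
                                    rank_fusion, regularized_rankings,
                                    task_labels, tune_acceptance_factors,
                                    two_stage_select)
from seqradiomics.simulate import TableSpec, generate_feature_table


# ---------------------------------------------------------------------------
# coarse-stage statistics
# ---------------------------------------------------------------------------

def test_pvalue_null_uniformity(rng):
    X = rng.standard_normal((80, 2000))
    y = np.repeat(["a", "b", "c", "d"], 20)
    p = per_feature_pvalues(X, y)
    assert 0.03 < (p < 0.05).mean() < 0.07
    # uniformity beyond the 5% tail
    assert sps.kstest(p, "uniform").pvalue > 1e-4


def test_pvalue_extreme_separation(rng):
    x = np.concatenate([rng.standard_normal(50), rng.standard_normal(50) + 10])
    y = np.repeat(["a", "b"], 50)
    assert per_feature_pvalues(x.reshape(-1, 1), y)[0] < 1e-10


def test_pvalue_constant_column_is_one():
    X = np.ones((40, 1))
    y = np.repeat(["a", "b"], 20)
    assert per_feature_pvalues(X, y)[0] == 1.0


def _univariate_lda_cv_bruteforce(x, y, folds, seed):
    """Independent per-fold loop implementing the same 1D discriminant."""
    from sklearn.model_selection import StratifiedKFold

    classes, yi = np.unique(y, return_inverse=True)
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    wrong = 0
    for train, test in skf.split(x.reshape(-1, 1), yi):
        mus, priors = [], []
        ss = 0.0
        for c in range(len(classes)):
            vals = x[train][yi[train] == c]
            mus.append(vals.mean())
            priors.append(len(vals) / len(train))
            ss += ((vals - vals.mean()) ** 2).sum()
        var = max(ss / max(1, len(train) - len(classes)), 1e-12)
        for i in test:
            scores = [x[i] * m / var - m * m / (2 * var) + np.log(pr)
                      for m, pr in zip(mus, priors)]
            if int(np.argmax(scores)) != yi[i]:
                wrong += 1
    return wrong / len(y)


def test_cv_error_matches_bruteforce(rng):
    y = np.repeat(["a", "b", "c", "d"], 15)
    X = rng.standard_normal((60, 6))
    fast = per_feature_cv_errors(X, y, folds=5, seed=3)
    for j in range(6):
        assert fast[j] == pytest.approx(
            _univariate_lda_cv_bruteforce(X[:, j], y, 5, 3), abs=1e-12)


def test_cv_error_separable_and_chance(rng):
    y = np.repeat(["a", "b"], 40)
    x = np.concatenate([np.zeros(40), np.ones(40) * 10]) \
        + 0.01 * rng.standard_normal(80)
    assert per_feature_cv_error(x, y) == 0.0
    y4 = np.repeat(["a", "b", "c", "d"], 50)
    noise = rng.standard_normal(200)
    err = np.mean([per_feature_cv_error(noise, y4, seed=s) for s in range(5)])
    assert abs(err - 0.75) < 0.1  # chance level for 4 balanced classes


def test_cv_error_deterministic(rng):
    x = rng.standard_normal(60)
    y = np.repeat(["a", "b"], 30)
    assert per_feature_cv_error(x, y, seed=4) == per_feature_cv_error(x, y, seed=4)


# ---------------------------------------------------------------------------
# elliptical gate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, e, a, b, expected", [
    (0.0, 0.0, 0.6, 0.85, True),     # origin interior
    (0.6, 0.0, 0.6, 0.85, False),    # on the boundary: strict < rejects
    (0.3, 0.4, 0.6, 0.85, True),     # 0.25 + 0.2215 = 0.4715 < 1
    (0.0, 0.85, 0.6, 0.85, False),   # boundary on the error axis
])
def test_ellipse_accept_examples(p, e, a, b, expected):
    assert ellipse_accept(p, e, a, b) is expected


def test_ellipse_accept_monotone(rng):
    a, b = 0.6, 0.85
    for _ in range(200):
        p2, e2 = rng.random(2)
        if ellipse_accept(p2, e2, a, b):
            p1, e1 = p2 * rng.random(), e2 * rng.random()
            assert ellipse_accept(p1, e1, a, b)


def test_ellipse_area_monotone_in_factors(rng):
    p = rng.random(500)
    e = rng.random(500)
    n1 = ellipse_accept(p, e, 0.3, 0.5).sum()
    n2 = ellipse_accept(p, e, 0.5, 0.5).sum()
    n3 = ellipse_accept(p, e, 0.5, 0.8).sum()
    assert n1 <= n2 <= n3


def test_tuner_degenerate_all_origin():
    p = np.zeros(50)
    e = np.zeros(50)
    # every grid point retains everything; tie-break forces (0.01, 0.01)
    assert tune_acceptance_factors(p, e) == (0.01, 0.01)


def test_tuner_hits_target_fraction(rng):
    p = rng.random(1000)
    e = rng.random(1000)
    a, b = tune_acceptance_factors(p, e, target_fraction=0.5)
    frac = ellipse_accept(p, e, a, b).mean()
    assert 0.45 <= frac <= 0.55


def test_tuner_single_criterion_matches_exhaustive():
    p = np.array([0.5])
    e = np.array([0.5])
    got = tune_acceptance_factors(p, e, target_fraction=1.0)
    # independent exhaustive scan with identical tie-breaks
    best = None
    for ai in range(1, 101):
        for bi in range(1, 101):
            a, b = ai * 0.01, bi * 0.01
            retained = 1 if (0.5 / a) ** 2 + (0.5 / b) ** 2 < 1 else 0
            key = (abs(retained - 1), a * b, a)
            if best is None or key < best[0]:
                best = (key, (round(a, 2), round(b, 2)))
    assert got == best[1]


# ---------------------------------------------------------------------------
# fine stage
# ---------------------------------------------------------------------------

def test_rank_fusion_examples():
    ranks = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
    np.testing.assert_array_equal(rank_fusion(ranks), [3.0, 6.0])
    # A = (1,3,3) -> 7 loses to B = (2,2,2) -> 6 despite a first place
    ranks = np.array([[1.0, 2.0], [3.0, 2.0], [3.0, 2.0]])
    fused = rank_fusion(ranks)
    assert fused[1] < fused[0]


def test_rank_fusion_order_invariant(rng):
    ranks = rng.integers(1, 10, size=(3, 6)).astype(float)
    np.testing.assert_array_equal(rank_fusion(ranks), rank_fusion(ranks[::-1]))


def test_regularized_rankings_planted_column(rng):
    hits = 0
    for s in range(10):
        r = np.random.default_rng(s)
        y = np.repeat(["a", "b"], 30)
        X = r.standard_normal((60, 30))
        X[:, 7] += np.where(y == "a", 2.0, -2.0)  # strongly aligned column
        Xs = (X - X.mean(0)) / X.std(0)
        ranks = regularized_rankings(Xs, y, seed=s)
        hits += all(ranks[m][7] == 1.0 for m in range(3))
    assert hits >= 9


def test_ridge_splits_duplicated_informative_column(rng):
    y = np.repeat(["a", "b"], 40)
    X = rng.standard_normal((80, 20))
    X[:, 3] += np.where(y == "a", 1.5, -1.5)
    X[:, 4] = X[:, 3] + 1e-6 * rng.standard_normal(80)
    Xs = (X - X.mean(0)) / X.std(0)
    ranks = regularized_rankings(Xs, y, seed=0)
    ridge = ranks[1]
    assert set(np.argsort(ridge)[:2]) == {3, 4}


def test_correlation_prune_examples(rng):
    X = rng.standard_normal((100, 6))
    X[:, 1] = X[:, 0]  # duplicate
    kept = correlation_prune(X, np.arange(6), threshold=0.4)
    assert 0 in kept and 1 not in kept
    X_ind = rng.standard_normal((400, 10))
    assert correlation_prune(X_ind, np.arange(10), 0.4, final_count=4) \
        == [0, 1, 2, 3]


def test_correlation_prune_one_survivor_per_block():
    spec = TableSpec(n_subjects=300, n_features=16, n_informative=0,
                     n_correlated_blocks=4, block_size=4,
                     block_correlation=0.8, seed=6)
    X = generate_feature_table(spec).values
    kept = correlation_prune(X, np.arange(16), threshold=0.4)
    for block in range(4):
        members = set(range(block * 4, block * 4 + 4))
        assert len(members & set(kept)) == 1


def test_correlation_prune_matches_bruteforce(rng):
    X = rng.standard_normal((50, 12))
    X[:, 5] = X[:, 2] * 0.9 + 0.1 * rng.standard_normal(50)
    order = rng.permutation(12)
    kept = correlation_prune(X, order, threshold=0.4, final_count=6)
    # independent greedy scan
    expected = []
    for j in order:
        if all(abs(np.corrcoef(X[:, j], X[:, k])[0, 1]) <= 0.4
               for k in expected):
            expected.append(int(j))
            if len(expected) == 6:
                break
    assert kept == expected


# ---------------------------------------------------------------------------
# composed selector
# ---------------------------------------------------------------------------

def test_two_stage_small_p_degenerate(rng):
    # fewer features than top_k: no error, final is a subset of all columns
    X = rng.standard_normal((60, 12))
    y = np.repeat(["TN", "nonTN"], 30)
    X[:, 0] += np.where(y == "TN", 1.5, 0.0)
    sel = TwoStageSelector(task="tn_binary", top_k=40, final_count=8,
                           seed=0).fit(X, y)
    assert set(sel.get_support(indices=True)) <= set(range(12))
    assert sel.transform(X).shape[1] == len(sel.final_idx_)


def test_two_stage_reproducible(planted_table):
    cfg = PipelineConfig(task="four_class", seed=9)
    _, r1 = two_stage_select(planted_table, cfg)
    _, r2 = two_stage_select(planted_table, cfg)
    assert r1.final == r2.final
    assert r1.top_k == r2.top_k


def test_final_set_satisfies_correlation_invariant(planted_table):
    cfg = PipelineConfig(task="four_class", seed=9)
    sel, res = two_stage_select(planted_table, cfg)
    X = planted_table.values[:, sel.final_idx_]
    C = np.corrcoef(X.T)
    off = np.abs(C[~np.eye(len(res.final), dtype=bool)])
    assert (off <= cfg.corr_threshold + 1e-12).all()
    # nesting invariant: final within top_k within coarse-accepted
    assert set(res.final) <= set(res.top_k) <= set(res.coarse_accepted)


# ---------------------------------------------------------------------------
# Rad-score
# ---------------------------------------------------------------------------

def test_radscore_single_feature_linear(rng):
    x = rng.standard_normal(80)
    y = np.where(x + 0.3 * rng.standard_normal(80) > 0, "TN", "nonTN")
    model = RadScoreModel().fit(x.reshape(-1, 1), y)
    xs = (x - model.mean_[0]) / model.scale_[0]
    expected = model.coefficients_[0] * xs + model.intercept_
    np.testing.assert_allclose(model.decision_function(x.reshape(-1, 1)),
                               expected, rtol=1e-10)


def test_radscore_orders_groups(rng):
    spec = TableSpec(n_subjects=134, n_features=8, n_informative=0, seed=1)
    table = generate_feature_table(spec)
    y = task_labels(table.labels, "tn_binary")
    X = table.values.copy()
    X[:, 0] += np.where(y == "TN", 2.0, 0.0)
    model = RadScoreModel().fit(X, y)
    s = model.decision_function(X)
    assert s[y == "TN"].mean() > s[y == "nonTN"].mean()


def test_radscore_invariant_to_column_rescaling(rng):
    X = rng.standard_normal((100, 4))
    y = np.where(X[:, 0] + 0.5 * rng.standard_normal(100) > 0, "TN", "nonTN")
    m1 = RadScoreModel().fit(X, y)
    X2 = X.copy()
    X2[:, 1] *= 2.0  # standardization absorbs the rescaling
    m2 = RadScoreModel().fit(X2, y)
    np.testing.assert_allclose(m1.decision_function(X),
                               m2.decision_function(X2), rtol=1e-6)


def test_radscore_four_class_axis(rng):
    spec = TableSpec(n_subjects=134, n_features=6, n_informative=3,
                     effect_size=1.0, seed=2)
    table = generate_feature_table(spec)
    model = RadScoreModel().fit(table.values, np.asarray(table.labels))
    assert model.coefficients_.shape == (6,)
    scores = model.decision_function(table.values)
    assert np.isfinite(scores).all()
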