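import numpy as np
import pytest

from hccscreen import CartScreen, ForestScreen, LogisticScreen
from hccscreen.errors import SeparationWarning


# ---------------------------------------------------------------------------
# logistic regression


def test_intercept_only_closed_form():
    y = np.r_[np.ones(3), np.zeros(7)]
    res = LogisticScreen(y, np.empty((10, 0))).fit()
    assert res.intercept == pytest.approx(np.log(3 / 7), abs=1e-6)
    assert res.converged


def test_two_by_two_closed_form_slope():
    """Single binary predictor: slope is the log odds-ratio of the 2x2
    exposure table, intercept the unexposed log-odds."""
    n11, n10 = 75, 54  # exposed / unexposed among positives
    n01, n00 = 308, 85  # exposed / unexposed among negatives
    x = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    y = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    res = LogisticScreen(y, x).fit()
    assert res.coefficients[0] == pytest.approx(
        np.log((n11 * n00) / (n10 * n01)), abs=1e-6
    )
    assert res.intercept == pytest.approx(np.log(n10 / n00), abs=1e-6)


def test_sigmoid_prediction_value():
    model = LogisticScreen([0, 1], [[0.0], [1.0]])  # container only; not fitted
    from hccscreen.learners import LogisticResults

    r = LogisticResults(
        model=model,
        intercept=0.5,
        coefficients=np.array([1.0]),
        bse=np.array([np.nan, np.nan]),
        cov_params=np.empty((2, 2)),
        converged=True,
        separated=False,
        n_iter=1,
        llf=np.nan,
    )
    assert r.predict(np.array([[0.0]]))[0] == pytest.approx(0.6224593312, abs=1e-9)
    zero = LogisticResults(
        model=model, intercept=0.0, coefficients=np.array([0.0]),
        bse=np.array([np.nan, np.nan]), cov_params=np.empty((2, 2)),
        converged=True, separated=False, n_iter=1, llf=np.nan,
    )
    assert (zero.predict(np.zeros((5, 1))) == 0.5).all()


def test_positive_slope_prediction_monotone(rng):
    x = rng.normal(size=200)
    y = (x + rng.normal(scale=0.5, size=200) > 0).astype(int)
    res = LogisticScreen(y, x).fit()
    assert res.coefficients[0] > 0
    grid = np.linspace(-3, 3, 50)[:, None]
    assert (np.diff(res.predict(grid)) >= 0).all()


def test_separation_warning_and_capped_coefficients():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = np.r_[np.zeros(10), np.ones(10)]
    with pytest.warns(SeparationWarning):
        res = LogisticScreen(y, x).fit()
    assert res.separated
    assert np.isfinite(res.params).all()
    p = res.predict(x[:, None])
    assert ((p > 0) & (p < 1)).all()


def test_single_class_rejected():
    with pytest.raises(ValueError):
        LogisticScreen(np.ones(5), np.random.default_rng(0).normal(size=(5, 2)))


def test_feature_count_mismatch_rejected(rng):
    y = rng.integers(0, 2, 30)
    y[:2] = [0, 1]
    res = LogisticScreen(y, rng.normal(size=(30, 3))).fit()
    with pytest.raises(ValueError):
        res.predict(rng.normal(size=(4, 2)))


def test_parameter_recovery_within_three_se(rng):
    """Simulated data from a known logistic model, n = 50,000: the fit
    recovers every coefficient within 3 standard errors."""
    true_beta = np.array([-1.0, 0.8, -0.5, 0.3])
    X = rng.normal(size=(50_000, 3))
    eta = true_beta[0] + X @ true_beta[1:]
    y = (rng.random(50_000) < 1 / (1 + np.exp(-eta))).astype(float)
    res = LogisticScreen(y, X).fit()
    assert res.converged
    assert (np.abs(res.params - true_beta) < 3 * res.bse).all()


def test_irls_matches_statsmodels(rng):
    """Independent cross-check of the IRLS route against statsmodels GLM."""
    sm = pytest.importorskip("statsmodels.api")
    X = rng.normal(size=(300, 2))
    y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + X[:, 0])))).astype(float)
    ours = LogisticScreen(y, X).fit()
    theirs = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.params, theirs.params, atol=1e-6)
    np.testing.assert_allclose(ours.bse, theirs.bse, rtol=1e-4)


# ---------------------------------------------------------------------------
# CART


def _replicate(x, y, times):
    return np.tile(x, times)[:, None], np.tile(y, times)


def test_pure_labels_single_leaf():
    X, y = _replicate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], 10)
    res = CartScreen(y, X).fit(seed=0)
    assert res.n_leaves == 1
    assert (res.predict(X) == 1.0).all()


def test_one_dimensional_split_threshold():
    """x = 1,2,3,4 with labels 0,0,1,1 (replicated past the minimum split
    size): the root threshold falls in (2, 3] and the children are pure."""
    X, y = _replicate([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], 10)
    res = CartScreen(y, X).fit(seed=0)
    node = res.to_dict()["nodes"][0]
    assert not node["leaf"]
    assert 2.0 < node["threshold"] <= 3.0
    pred = res.predict(np.array([[1.0], [2.0], [3.0], [4.0]]))
    np.testing.assert_array_equal(pred, [0.0, 0.0, 1.0, 1.0])


def test_gini_impurity_of_root_matches_hand_computation():
    """A 6/4 node has Gini impurity 1 - 0.6^2 - 0.4^2 = 0.48."""
    X = np.zeros((10, 1))
    y = np.r_[np.ones(6), np.zeros(4)].astype(int)
    res = CartScreen(y, X, min_samples_split=2, min_samples_leaf=1).fit(seed=0)
    assert res.tree.tree_.impurity[0] == pytest.approx(0.48)


def test_distinct_predictions_bounded_by_leaf_count(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    res = CartScreen(y, X).fit(seed=1)
    preds = res.predict(X)
    assert len(np.unique(preds)) <= res.n_leaves


def test_pruning_sequence_is_nested(small_cohort):
    """Larger complexity penalties prune to subtrees: leaf counts are
    non-increasing along the cost-complexity path."""
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    model = CartScreen(y, X)
    full = model._grow(X, y, 0.0, seed=0)
    path = full.cost_complexity_pruning_path(X, y)
    leaves = [
        model._grow(X, y, a, seed=0).get_n_leaves() for a in path.ccp_alphas
    ]
    assert (np.diff(leaves) <= 0).all()


def test_cart_cp_selected_comes_from_path(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    res = CartScreen(y, X).fit(seed=3)
    assert res.cp_selected >= 0
    assert res.n_leaves <= model_leaves_unpruned(X, y)


def model_leaves_unpruned(X, y):
    from sklearn.tree import DecisionTreeClassifier

    t = DecisionTreeClassifier(min_samples_split=20, min_samples_leaf=7, random_state=0)
    t.fit(X, y)
    return t.get_n_leaves()


# ---------------------------------------------------------------------------
# forest


def test_single_tree_forest_equals_its_tree(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    res = ForestScreen(y, X, ntree=1, mtry=2).fit(seed=5)
    np.testing.assert_array_equal(res.predict(X), res.tree_predict(0, X))


def test_forest_determinism_and_seed_sensitivity(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    a = ForestScreen(y, X, ntree=20).fit(seed=1)
    b = ForestScreen(y, X, ntree=20).fit(seed=1)
    c = ForestScreen(y, X, ntree=20).fit(seed=2)
    np.testing.assert_array_equal(a.predict(X), b.predict(X))
    assert not np.array_equal(a.oob_mask, c.oob_mask)


def test_oob_fraction_near_bootstrap_expectation(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    res = ForestScreen(y, X, ntree=100).fit(seed=7)
    n = len(y)
    assert res.oob_fraction == pytest.approx((1 - 1 / n) ** n, abs=0.02)
    assert res.oob_fraction == pytest.approx(0.368, abs=0.02)


def test_forest_prediction_is_tree_average_and_convex(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    res = ForestScreen(y, X, ntree=15).fit(seed=9)
    per_tree = np.stack([res.tree_predict(b, X[:10]) for b in range(15)])
    np.testing.assert_allclose(res.predict(X[:10]), per_tree.mean(axis=0))
    assert (res.predict(X[:10]) <= per_tree.max(axis=0) + 1e-12).all()
    assert (res.predict(X[:10]) >= per_tree.min(axis=0) - 1e-12).all()


def test_mtry_exceeding_feature_count_rejected(small_cohort):
    X = small_cohort.feature_matrix()
    y = small_cohort.labels
    with pytest.raises(ValueError, match="mtry"):
        ForestScreen(y, X, mtry=5)


def test_forest_beats_single_tree_on_separable_data():
    """Median validation AUC over seeds: the bagged forest is at least as
    good as one pruned tree on held-out synthetic data (the ensemble
    ordering the study reports)."""
    from hccscreen import ScoredCohort, auc_scores, default_study_spec, generate_cohort

    forest_aucs, cart_aucs = [], []
    for seed in range(8):
        spec = default_study_spec(seed=100 + seed)
        spec.n_hcc, spec.n_cirrhosis, spec.n_hepatitis = 137, 207, 224
        c = generate_cohort(spec)
        X, y = c.feature_matrix(), c.labels
        train = np.arange(len(y)) % 4 != 0
        f = ForestScreen(y[train], X[train], ntree=150).fit(seed=seed)
        t = CartScreen(y[train], X[train]).fit(seed=seed)
        forest_aucs.append(auc_scores(ScoredCohort(f.predict(X[~train]), y[~train])))
        cart_aucs.append(auc_scores(ScoredCohort(t.predict(X[~train]), y[~train])))
    assert np.median(forest_aucs) >= np.median(cart_aucs)
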