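"""The three elementary classifiers behind the screening panel.

Each follows the model/results convention: a model object is constructed
from the training data, ``fit()`` returns an immutable results object that
carries the fitted parameters plus diagnostics and exposes
``predict(X)`` (class-1 probabilities) and ``summary()``.

* :class:`LogisticScreen` — binomial logistic regression fitted by
  iteratively reweighted least squares (IRLS), with explicit handling of
  complete separation (warn and cap at the last stable iterate).
* :class:`CartScreen` — a Gini classification tree grown with the
  conventional recursive-partitioning controls (minimum 20 subjects to
  split, minimum leaf size 7) and pruned by cost-complexity at the value
  minimizing the internally cross-validated misclassification error
  ("xerror"), ties broken toward the more aggressive pruning.
* :class:`ForestScreen` — a Breiman-style bagged forest of unpruned Gini
  trees (default 500 trees, 2 candidate features per split) with per-tree
  bootstrap and out-of-bag bookkeeping; the forest probability is the
  unweighted mean of the trees' leaf probabilities.

Individual trees are grown by scikit-learn's ``DecisionTreeClassifier``;
the pruning-selection and bagging logic around them lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import SeparationWarning

__all__ = [
    "LogisticScreen",
    "LogisticResults",
    "CartScreen",
    "CartResults",
    "ForestScreen",
    "ForestResults",
]

_SIGMOID_CLIP = 700.0  # exp overflow guard


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_SIGMOID_CLIP, _SIGMOID_CLIP)))


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_training(X: np.ndarray, y: np.ndarray) -> None:
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be 0/1")


# ---------------------------------------------------------------------------
# Logistic regression


class LogisticScreen:
    """Binomial logistic regression model, maximum likelihood via IRLS."""

    def __init__(self, y, X, feature_names: list[str] | None = None):
        self.X = _as_matrix(X)
        self.y = np.asarray(y, dtype=float)
        _check_training(self.X, self.y)
        if len(np.unique(self.y)) < 2:
            raise ValueError("logistic fit requires both classes present")
        self.feature_names = list(
            feature_names
            if feature_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")

    def fit(self, tol: float = 1e-8, maxiter: int = 25) -> "LogisticResults":
        """IRLS until the largest coefficient change drops below ``tol``
        or ``maxiter`` iterations. On (quasi-)complete separation the last
        stable iterate is returned with a :class:`SeparationWarning`."""
        X = np.column_stack([np.ones(len(self.X)), self.X])
        y = self.y
        beta = np.zeros(X.shape[1])
        converged = False
        separated = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            eta = X @ beta
            mu = _sigmoid(eta)
            w = mu * (1.0 - mu)
            # Separation shows up as fitted probabilities pinned at 0/1 on
            # perfectly classified points with exploding coefficients.
            if w.max() < 1e-10 or np.abs(beta).max() > 1e4:
                separated = True
                break
            z = eta + (y - mu) / np.maximum(w, 1e-10)
            xtw = X.T * w
            try:
                beta_new = np.linalg.solve(xtw @ X, xtw @ z)
            except np.linalg.LinAlgError:
                separated = True
                break
            delta = np.abs(beta_new - beta).max()
            beta = beta_new
            if delta < tol:
                converged = True
                break
        if not converged and not separated:
            # diverging deviance with huge coefficients also signals separation
            if np.abs(beta).max() > 1e3:
                separated = True
        if separated:
            warnings.warn(
                "complete or quasi-complete separation detected; "
                "coefficients capped at last stable IRLS iterate",
                SeparationWarning,
                stacklevel=2,
            )
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        xtwx = (X.T * np.maximum(w, 1e-12)) @ X
        try:
            cov = np.linalg.inv(xtwx)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((X.shape[1], X.shape[1]), np.nan)
            bse = np.full(X.shape[1], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        return LogisticResults(
            model=self,
            intercept=float(beta[0]),
            coefficients=beta[1:].copy(),
            bse=bse,
            cov_params=cov,
            converged=converged,
            separated=separated,
            n_iter=n_iter,
            llf=ll,
        )


@dataclass(frozen=True)
class LogisticResults:
    model: LogisticScreen
    intercept: float
    coefficients: np.ndarray
    bse: np.ndarray  # [intercept, coefficients...]
    cov_params: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    llf: float

    @property
    def params(self) -> np.ndarray:
        """[intercept, slope_1, ..., slope_p]."""
        return np.concatenate([[self.intercept], self.coefficients])

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != len(self.coefficients):
            raise ValueError(
                f"expected {len(self.coefficients)} features, got {X.shape[1]}"
            )
        return _sigmoid(self.intercept + X @ self.coefficients)

    def summary(self) -> str:
        lines = [
            "Logistic regression (IRLS)",
            f"  converged: {self.converged}  iterations: {self.n_iter}"
            + ("  [separation warning]" if self.separated else ""),
            f"  log-likelihood: {self.llf:.4f}",
            f"  {'term':<12}{'coef':>12}{'std err':>12}",
            f"  {'intercept':<12}{self.intercept:>12.4f}{self.bse[0]:>12.4f}",
        ]
        for name, b, se in zip(
            self.model.feature_names, self.coefficients, self.bse[1:]
        ):
            lines.append(f"  {name:<12}{b:>12.4f}{se:>12.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "logistic",
            "feature_names": self.model.feature_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
        }


# ---------------------------------------------------------------------------
# CART


class CartScreen:
    """Classification tree with cost-complexity pruning selected by
    internal cross-validation of the misclassification error."""

    def __init__(
        self,
        y,
        X,
        feature_names: list[str] | None = None,
        min_samples_split: int = 20,
        min_samples_leaf: int = 7,
    ):
        self.X = _as_matrix(X)
        self.y = np.asarray(y, dtype=int)
        _check_training(self.X, self.y)
        self.feature_names = list(
            feature_names
            if feature_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf

    def _grow(self, X, y, ccp_alpha: float = 0.0, seed: int = 0):
        tree = DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            ccp_alpha=ccp_alpha,
            random_state=seed,
        )
        tree.fit(X, y)
        return tree

    def fit(self, k_internal: int = 10, seed: int = 0) -> "CartResults":
        """Grow the full tree, then prune at the complexity value whose
        ``k_internal``-fold cross-validated misclassification rate is
        minimal (ties resolved toward the larger complexity, i.e. the
        smaller tree). A single-class training set yields a single leaf."""
        X, y = self.X, self.y
        if len(np.unique(y)) < 2:
            return CartResults(
                model=self,
                tree=None,
                constant=float(y.mean()),
                cp_selected=0.0,
                cp_table=np.zeros((0, 2)),
            )
        full = self._grow(X, y, 0.0, seed)
        path = full.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) == 1:
            chosen = float(alphas[0])
        else:
            xerror = self._cv_error(alphas, k_internal, seed)
            best = xerror.min()
            # ties -> larger alpha (more pruning)
            chosen = float(alphas[np.flatnonzero(xerror <= best + 1e-12)[-1]])
        pruned = self._grow(X, y, chosen, seed)
        return CartResults(
            model=self,
            tree=pruned,
            constant=None,
            cp_selected=chosen,
            cp_table=np.column_stack(
                [alphas, self._last_xerror if len(alphas) > 1 else [np.nan]]
            ),
        )

    def _cv_error(self, alphas: np.ndarray, k: int, seed: int) -> np.ndarray:
        """Internal stratified CV misclassification per pruning value."""
        from .crossval import stratified_fold_indices

        X, y = self.X, self.y
        k = min(k, int(np.bincount(y).min()))
        k = max(k, 2)
        folds = stratified_fold_indices(y, k, seed)
        errors = np.zeros(len(alphas))
        for f in range(k):
            val = folds == f
            if len(np.unique(y[~val])) < 2:
                continue
            for j, a in enumerate(alphas):
                t = self._grow(X[~val], y[~val], a, seed)
                errors[j] += np.sum(t.predict(X[val]) != y[val])
        self._last_xerror = errors / len(y)
        return self._last_xerror


@dataclass(frozen=True)
class CartResults:
    model: CartScreen
    tree: object  # fitted sklearn tree, or None when degenerate
    constant: float | None
    cp_selected: float
    cp_table: np.ndarray  # columns: alpha, cross-validated error

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError("feature count mismatch")
        if self.tree is None:
            return np.full(len(X), self.constant)
        proba = self.tree.predict_proba(X)
        idx = list(self.tree.classes_).index(1) if 1 in self.tree.classes_ else None
        return proba[:, idx] if idx is not None else np.zeros(len(X))

    @property
    def n_leaves(self) -> int:
        return 1 if self.tree is None else int(self.tree.get_n_leaves())

    def summary(self) -> str:
        return (
            "Classification tree (Gini, cost-complexity pruned)\n"
            f"  leaves: {self.n_leaves}  cp selected: {self.cp_selected:.6g}\n"
            f"  pruning values examined: {len(self.cp_table)}"
        )

    def to_dict(self) -> dict:
        """Node-list serialization: feature index and threshold for internal
        nodes (children by node index), class-1 probability and n for
        leaves."""
        if self.tree is None:
            return {
                "kind": "cart",
                "cp_selected": self.cp_selected,
                "nodes": [
                    {"leaf": True, "prob": self.constant, "n": len(self.model.y)}
                ],
            }
        t = self.tree.tree_
        col = list(self.tree.classes_).index(1) if 1 in self.tree.classes_ else None
        nodes = []
        for i in range(t.node_count):
            if t.children_left[i] == -1:
                prob = 0.0 if col is None else float(t.value[i][0][col])
                nodes.append(
                    {"leaf": True, "prob": prob, "n": int(t.n_node_samples[i])}
                )
            else:
                nodes.append(
                    {
                        "leaf": False,
                        "feature": int(t.feature[i]),
                        "threshold": float(t.threshold[i]),
                        "left": int(t.children_left[i]),
                        "right": int(t.children_right[i]),
                    }
                )
        return {"kind": "cart", "cp_selected": self.cp_selected, "nodes": nodes}


# ---------------------------------------------------------------------------
# Random forest (bagged Gini trees)


class ForestScreen:
    """Bagged ensemble of unpruned classification trees.

    Each tree sees an n-out-of-n bootstrap of the training subjects and, at
    every split, a random subset of ``mtry`` candidate features. Subjects
    left out of a tree's bootstrap are recorded as its out-of-bag set.
    """

    def __init__(
        self,
        y,
        X,
        feature_names: list[str] | None = None,
        ntree: int = 500,
        mtry: int = 2,
    ):
        self.X = _as_matrix(X)
        self.y = np.asarray(y, dtype=int)
        _check_training(self.X, self.y)
        if len(np.unique(self.y)) < 2:
            raise ValueError("forest fit requires both classes present")
        if mtry > self.X.shape[1]:
            raise ValueError(
                f"mtry={mtry} exceeds the {self.X.shape[1]} available features"
            )
        if ntree < 1:
            raise ValueError("ntree must be >= 1")
        self.feature_names = list(
            feature_names
            if feature_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.ntree = ntree
        self.mtry = mtry

    def fit(self, seed: int = 0) -> "ForestResults":
        rng = np.random.default_rng(seed)
        n = len(self.y)
        trees = []
        class1_col = []
        oob = np.zeros((self.ntree, n), dtype=bool)
        for b in range(self.ntree):
            idx = rng.integers(0, n, size=n)
            oob[b] = ~np.isin(np.arange(n), idx)
            yb = self.y[idx]
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=self.mtry,
                min_samples_leaf=1,
                min_samples_split=2,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(self.X[idx], yb)
            trees.append(tree)
            classes = list(tree.classes_)
            class1_col.append(classes.index(1) if 1 in classes else -1)
        return ForestResults(
            model=self,
            trees=tuple(trees),
            class1_col=tuple(class1_col),
            oob_mask=oob,
            seed=seed,
        )


@dataclass(frozen=True)
class ForestResults:
    model: ForestScreen
    trees: tuple
    class1_col: tuple  # per-tree column of class 1 in predict_proba (-1 = absent)
    oob_mask: np.ndarray  # (ntree, n_train) out-of-bag membership
    seed: int

    def tree_predict(self, b: int, X) -> np.ndarray:
        X = _as_matrix(X)
        col = self.class1_col[b]
        if col < 0:
            return np.zeros(len(X))
        return self.trees[b].predict_proba(X)[:, col]

    def predict(self, X) -> np.ndarray:
        """Unweighted mean of per-tree leaf class-1 probabilities."""
        X = _as_matrix(X)
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError("feature count mismatch")
        if not self.trees:
            raise ValueError("empty forest")
        total = np.zeros(len(X))
        for b in range(len(self.trees)):
            total += self.tree_predict(b, X)
        return total / len(self.trees)

    @property
    def oob_fraction(self) -> float:
        """Mean fraction of subjects out-of-bag per tree (~ (1-1/n)^n)."""
        return float(self.oob_mask.mean())

    def summary(self) -> str:
        return (
            "Bagged classification forest\n"
            f"  trees: {len(self.trees)}  mtry: {self.model.mtry}  "
            f"seed: {self.seed}\n"
            f"  mean out-of-bag fraction: {self.oob_fraction:.3f}"
        )
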