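"""ML comparators for survival-months regression, with fixed hyperparameters.

Four model families, each regressing observed overall survival (months) on
the feature table, restricted to subjects whose death was observed:

* ``ann`` — one hidden layer of floor((n_features + 1) / 2) sigmoid units,
  linear output, full-batch gradient descent with momentum 0.5, 200
  iterations, learning rate 0.01;
* ``svr_rbf`` — epsilon-SVR with Gaussian kernel (epsilon 0.01 on
  normalized data, gamma 1.0, C 0.001);
* ``svr_rff`` — the Gaussian kernel (gamma 1.0) linearized by 200 random
  Fourier components, fitted by SGD with squared-epsilon loss (epsilon
  0.01, trade-off 0.01);
* ``regression_tree`` — variance-reduction splitting, maximal depth 5,
  minimal decrease 0.1 (on normalized-variance scale), grown on a random
  half of the training rows and pruned bottom-up on the held-out half
  (50-50 reduced-error pruning).

Feature normalization is min-max to [0, 1], learned on training rows only.
Predicted OS is a higher-is-better prognostic score.

Also here: random-forest (extremely randomized trees) feature scoring with
the baseline-beating RMSE filter, the 20-fold cross-validated attribute
search, and a PCA wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import SGDRegressor
from sklearn.svm import SVR

from .survstats import SurvivalSample, concordance_index
from .olpm import dichotomized_cindex_sweep

__all__ = [
    "MLConfig",
    "TrainedModel",
    "train_model",
    "predict",
    "rf_feature_scores",
    "cv_attribute_search",
    "pca_scores",
    "rff_map",
]

ModelKind = Literal["ann", "svr_rbf", "svr_rff", "regression_tree"]

#: printed extremely-randomized-forest constants for the feature pre-filter
RF_DEFAULTS = dict(
    n_estimators=10,
    max_depth=5,
    min_samples_leaf=20,
    min_samples_split=40,
    min_impurity_decrease=0.1,
)


@dataclass(frozen=True)
class MLConfig:
    """Model kind + hyperparameters; defaults are the study's fixed values."""

    kind: ModelKind
    seed: int = 0
    # ann
    ann_iterations: int = 200
    ann_learning_rate: float = 0.01
    ann_momentum: float = 0.5
    # svr_rbf
    svr_epsilon: float = 0.01
    svr_gamma: float = 1.0
    svr_c: float = 0.001
    # svr_rff
    rff_components: int = 200
    rff_gamma: float = 1.0
    rff_epsilon: float = 0.01
    rff_tradeoff: float = 0.01
    # regression_tree
    tree_max_depth: int = 5
    tree_min_decrease: float = 0.1
    normalization: Literal["minmax", "zscore"] = "minmax"


@dataclass(frozen=True)
class _Normalizer:
    """Per-feature affine map learned on training rows only."""

    shift: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...]

    @classmethod
    def fit(cls, X: pd.DataFrame, kind: str) -> "_Normalizer":
        arr = X.to_numpy(dtype=float)
        if kind == "minmax":
            lo = arr.min(axis=0)
            rng = arr.max(axis=0) - lo
            rng[rng == 0] = 1.0
            return cls(lo, rng, tuple(X.columns))
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        return cls(mu, sd, tuple(X.columns))

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {', '.join(missing)}")
        arr = X[list(self.feature_names)].to_numpy(dtype=float)
        return (arr - self.shift) / self.scale


# ---------------------------------------------------------------------------
# ANN
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class _ANN:
    """1-hidden-layer perceptron, sigmoid hidden / linear output.

    Weights initialized uniform in +/- 1/sqrt(fan-in) from the seed;
    trained by full-batch gradient descent on mean squared error with
    classical momentum.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    loss_trajectory: list = field(default_factory=list)

    @classmethod
    def train(cls, X: np.ndarray, y: np.ndarray, config: MLConfig) -> "_ANN":
        rng = np.random.default_rng(config.seed)
        n, f = X.shape
        hidden = max(1, (f + 1) // 2)
        lim1, lim2 = 1.0 / np.sqrt(f), 1.0 / np.sqrt(hidden)
        w1 = rng.uniform(-lim1, lim1, size=(f, hidden))
        b1 = rng.uniform(-lim1, lim1, size=hidden)
        w2 = rng.uniform(-lim2, lim2, size=hidden)
        b2 = rng.uniform(-lim2, lim2)
        net = cls(w1, b1, w2, float(b2))
        v = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]
        lr, mom = config.ann_learning_rate, config.ann_momentum
        for _ in range(config.ann_iterations):
            h = _sigmoid(X @ net.w1 + net.b1)
            pred = h @ net.w2 + net.b2
            err = pred - y
            net.loss_trajectory.append(float(np.mean(err**2)))
            g_out = 2.0 * err / n
            gw2 = h.T @ g_out
            gb2 = float(g_out.sum())
            g_h = np.outer(g_out, net.w2) * h * (1.0 - h)
            gw1 = X.T @ g_h
            gb1 = g_h.sum(axis=0)
            v[0] = mom * v[0] - lr * gw1
            v[1] = mom * v[1] - lr * gb1
            v[2] = mom * v[2] - lr * gw2
            v[3] = mom * v[3] - lr * gb2
            net.w1 += v[0]
            net.b1 += v[1]
            net.w2 += v[2]
            net.b2 += v[3]
        h = _sigmoid(X @ net.w1 + net.b1)
        net.loss_trajectory.append(float(np.mean((h @ net.w2 + net.b2 - y) ** 2)))
        return net

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.w1 + self.b1) @ self.w2 + self.b2

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]


# ---------------------------------------------------------------------------
# Random Fourier features
# ---------------------------------------------------------------------------

def rff_map(n_features: int, n_components: int, gamma: float, seed: int):
    """Random Fourier feature map approximating exp(-gamma * ||a - b||^2).

    Returns (W, b, transform) with frequencies W ~ N(0, 2*gamma*I) and
    phases b ~ U(0, 2*pi); z(x) = sqrt(2/D) * cos(x W + b) satisfies
    E[z(a).z(b)] = exp(-gamma * ||a - b||^2).
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, np.sqrt(2.0 * gamma), size=(n_features, n_components))
    b = rng.uniform(0.0, 2.0 * np.pi, size=n_components)

    def transform(X: np.ndarray) -> np.ndarray:
        return np.sqrt(2.0 / n_components) * np.cos(X @ W + b)

    return W, b, transform


# ---------------------------------------------------------------------------
# Regression tree with 50-50 reduced-error pruning
# ---------------------------------------------------------------------------

@dataclass
class _TreeNode:
    value: float
    feature: int | None = None
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _grow_tree(X, y, depth, max_depth, min_decrease, n_total) -> _TreeNode:
    node = _TreeNode(value=float(y.mean()))
    n = y.size
    if depth >= max_depth or n < 2:
        return node
    parent_impurity = float(y.var()) * n
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        total, total_sq = csum[-1], csq[-1]
        for k in range(1, n):
            if xs[k] == xs[k - 1]:
                continue
            left_imp = csq[k - 1] - csum[k - 1] ** 2 / k
            nr = n - k
            right_imp = (total_sq - csq[k - 1]) - (total - csum[k - 1]) ** 2 / nr
            decrease = parent_impurity - left_imp - right_imp
            if best is None or decrease > best[0]:
                best = (decrease, j, 0.5 * (xs[k] + xs[k - 1]))
    # minimal decrease in the variance measure, weighted by the node's share
    # of the sample (months^2 units, as in forest implementations): the SSE
    # drop divided by the total training count must reach the knob
    if best is None or best[0] / n_total < min_decrease:
        return node
    _, j, thr = best
    mask = X[:, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow_tree(X[mask], y[mask], depth + 1, max_depth,
                           min_decrease, n_total)
    node.right = _grow_tree(X[~mask], y[~mask], depth + 1, max_depth,
                            min_decrease, n_total)
    return node


def _tree_predict(node: _TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        cur = node
        while not cur.is_leaf:
            cur = cur.left if row[cur.feature] <= cur.threshold else cur.right
        out[i] = cur.value
    return out


def _prune_tree(node: _TreeNode, X_val, y_val) -> _TreeNode:
    """Bottom-up reduced-error pruning on a held-out half.

    A subtree is collapsed to its leaf only on positive evidence: the leaf
    must have strictly lower held-out SSE. Nodes no validation row reaches
    are left as grown (no evidence either way).
    """
    if node.is_leaf or y_val.size == 0:
        return node
    mask = X_val[:, node.feature] <= node.threshold
    node.left = _prune_tree(node.left, X_val[mask], y_val[mask])
    node.right = _prune_tree(node.right, X_val[~mask], y_val[~mask])
    subtree_sse = float(((y_val - _tree_predict(node, X_val)) ** 2).sum())
    leaf_sse = float(((y_val - node.value) ** 2).sum())
    if leaf_sse < subtree_sse:
        node.feature, node.left, node.right = None, None, None
    return node


@dataclass
class _RegressionTree:
    root: _TreeNode

    @classmethod
    def train(cls, X, y, config: MLConfig) -> "_RegressionTree":
        rng = np.random.default_rng(config.seed)
        n = y.size
        perm = rng.permutation(n)
        half = max(1, n // 2)
        grow_idx, prune_idx = perm[:half], perm[half:]
        root = _grow_tree(X[grow_idx], y[grow_idx], 0, config.tree_max_depth,
                          config.tree_min_decrease, half)
        if prune_idx.size:
            root = _prune_tree(root, X[prune_idx], y[prune_idx])
        return cls(root)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _tree_predict(self.root, X)


# ---------------------------------------------------------------------------
# Unified training surface
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted comparator: normalization + learned parameters.

    Predictions are months of OS (higher is better prognosis) and are a
    pure function of the stored state.
    """

    config: MLConfig
    normalizer: _Normalizer
    inner: object
    rff: tuple | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.normalizer.transform(X)
        if Z.shape[0] == 0:
            return np.empty(0)
        if self.config.kind == "svr_rff":
            _, _, transform = self.rff
            return self.inner.predict(transform(Z))
        return np.asarray(self.inner.predict(Z), dtype=float)


def train_model(
    config: MLConfig, X: pd.DataFrame, sample: SurvivalSample
) -> TrainedModel:
    """Fit one comparator on the event-observed subjects of a cohort.

    Censored rows are excluded (the regression target is observed OS in
    months); the normalizer is learned on the retained training rows only.
    """
    if X.shape[1] == 0:
        raise ValueError("no feature columns")
    if X.shape[0] != len(sample):
        raise ValueError("feature rows and survival sample differ in length")
    keep = sample.events
    X_train = X.loc[keep]
    y = sample.times[keep]
    if y.size < 2:
        raise ValueError("need at least two event-observed training subjects")
    norm = _Normalizer.fit(X_train, config.normalization)
    Z = norm.transform(X_train)

    if config.kind == "ann":
        inner = _ANN.train(Z, y, config)
        return TrainedModel(config, norm, inner)
    if config.kind == "svr_rbf":
        svr = SVR(kernel="rbf", C=config.svr_c, gamma=config.svr_gamma,
                  epsilon=config.svr_epsilon, tol=1e-6)
        svr.fit(Z, y)
        return TrainedModel(config, norm, svr)
    if config.kind == "svr_rff":
        rff = rff_map(Z.shape[1], config.rff_components, config.rff_gamma,
                      config.seed)
        sgd = SGDRegressor(
            loss="squared_epsilon_insensitive",
            epsilon=config.rff_epsilon,
            alpha=config.rff_tradeoff,
            random_state=config.seed,
            max_iter=1000,
            tol=1e-6,
        )
        sgd.fit(rff[2](Z), y)
        return TrainedModel(config, norm, sgd, rff=rff)
    if config.kind == "regression_tree":
        tree = _RegressionTree.train(Z, y, config)
        return TrainedModel(config, norm, tree)
    raise ValueError(f"unknown model kind: {config.kind!r}")


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted OS in months for new rows (schema-checked, no refitting)."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def rf_feature_scores(
    X: pd.DataFrame,
    sample: SurvivalSample,
    n_iterations: int = 10_000,
    test_fraction: float = 0.25,
    seed: int = 0,
    rf_params: dict | None = None,
) -> tuple[pd.Series, int]:
    """Summed impurity importances of baseline-beating forests.

    Repeats ``n_iterations`` times: randomly split the event-observed rows
    into train/test, fit an extremely randomized forest regressor, and if
    its test RMSE is at least 5% better than the baseline (predicting the
    training mean) add its per-feature impurity importances to the running
    totals. Returns (scores, number of qualifying iterations); all-zero
    scores with zero qualifying iterations is a valid outcome on pure
    noise.
    """
    params = dict(RF_DEFAULTS)
    if rf_params:
        params.update(rf_params)
    keep = sample.events
    Xe = X.loc[keep].to_numpy(dtype=float)
    y = sample.times[keep]
    n = y.size
    n_test = max(1, int(round(test_fraction * n)))
    if n - n_test < max(params["min_samples_split"], 2):
        raise ValueError("too few event-observed subjects for the forest minima")
    rng = np.random.default_rng(seed)
    scores = np.zeros(X.shape[1])
    qualifying = 0
    for i in range(n_iterations):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        forest = ExtraTreesRegressor(
            random_state=int(rng.integers(2**31 - 1)), **params
        )
        forest.fit(Xe[train_idx], y[train_idx])
        pred = forest.predict(Xe[test_idx])
        rmse = float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))
        baseline = float(
            np.sqrt(np.mean((y[train_idx].mean() - y[test_idx]) ** 2))
        )
        if rmse <= 0.95 * baseline:
            scores += forest.feature_importances_
            qualifying += 1
    return pd.Series(scores, index=X.columns, name="rf_score"), qualifying


@dataclass(frozen=True)
class CVSearchResult:
    best_subset: tuple[str, ...]
    mean_cindex: float
    mean_rmse: float
    threshold: float
    table: pd.DataFrame          # per-subset mean c-index / RMSE
    folds: tuple = ()            # held-out index arrays, one per fold


def cv_attribute_search(
    candidate_subsets: Sequence[Sequence[str]],
    X: pd.DataFrame,
    sample: SurvivalSample,
    n_folds: int = 20,
    holdout_size: int = 50,
    seed: int = 0,
    config: MLConfig | None = None,
    cindex_tolerance: float = 0.005,
) -> CVSearchResult:
    """Cross-validated attribute search for the neural network.

    For every candidate subset: over ``n_folds`` random folds each holding
    out ``holdout_size`` subjects, train the ANN on the remainder and
    record the held-out concordance index (predicted OS, higher is better)
    and RMSE on event-observed held-out subjects. The winner has the best
    mean RMSE among subsets within ``cindex_tolerance`` of the best mean
    c-index. The carried dichotomizing threshold is the best-c-index fold's
    optimal cutpoint of its test predictions.
    """
    if not candidate_subsets:
        raise ValueError("no candidate subsets")
    n = len(sample)
    if holdout_size >= n:
        raise ValueError("cohort smaller than the holdout size")
    base = config or MLConfig(kind="ann", seed=seed)
    rng = np.random.default_rng(seed)
    folds = [rng.permutation(n)[:holdout_size] for _ in range(n_folds)]

    rows = []
    thresholds: dict[tuple[str, ...], float] = {}
    for subset in candidate_subsets:
        subset = tuple(subset)
        cs, rmses = [], []
        best_fold_c, best_fold_thr = -np.inf, np.nan
        for f_idx, test_idx in enumerate(folds):
            test_mask = np.zeros(n, dtype=bool)
            test_mask[test_idx] = True
            fold_cfg = MLConfig(**{**base.__dict__, "seed": seed + 1000 * f_idx})
            model = train_model(
                fold_cfg, X.loc[~test_mask, list(subset)],
                sample.subset(~test_mask),
            )
            test_sample = sample.subset(test_mask)
            pred = model.predict(X.loc[test_mask, list(subset)])
            c = concordance_index(pred, test_sample, orientation="higher-is-better")
            ev = test_sample.events
            rmse = float(np.sqrt(np.mean((pred[ev] - test_sample.times[ev]) ** 2)))
            cs.append(c)
            rmses.append(rmse)
            if c > best_fold_c and np.ptp(pred) > 0:
                thr, _ = dichotomized_cindex_sweep(-pred, test_sample)
                best_fold_c, best_fold_thr = c, -thr
        rows.append((subset, float(np.mean(cs)), float(np.mean(rmses))))
        thresholds[subset] = best_fold_thr

    table = pd.DataFrame(rows, columns=["subset", "mean_cindex", "mean_rmse"])
    best_c = table["mean_cindex"].max()
    near = table[table["mean_cindex"] >= best_c - cindex_tolerance]
    winner = near.sort_values(
        ["mean_rmse", "mean_cindex"], ascending=[True, False], kind="stable"
    ).iloc[0]
    subset = tuple(winner["subset"])
    return CVSearchResult(
        best_subset=subset,
        mean_cindex=float(winner["mean_cindex"]),
        mean_rmse=float(winner["mean_rmse"]),
        threshold=float(thresholds[subset]),
        table=table,
        folds=tuple(folds),
    )


def pca_scores(X: pd.DataFrame) -> dict:
    """PCA of the standardized feature table (constant columns dropped).

    Returns components (orthonormal loadings), per-subject score matrix and
    the explained-variance ratios, for inspecting how survival-relevant
    attributes load on the leading components.
    """
    import warnings as _warnings

    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        _warnings.warn(f"dropping constant column(s): {', '.join(dropped)}",
                       stacklevel=2)
    if len(keep) == 0 or X.shape[0] < 2:
        raise ValueError("need >= 2 rows and >= 1 non-constant column")
    arr = X[keep].to_numpy(dtype=float)
    arr = (arr - arr.mean(axis=0)) / arr.std(axis=0)
    pca = PCA()
    scores = pca.fit_transform(arr)
    return {
        "feature_names": keep,
        "components": pca.components_,
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
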