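"""Regression-forest machinery for the driver analysis.

A from-scratch random forest for regression with the pieces the driver
analysis needs and that off-the-shelf wrappers tend to hide: out-of-bag (OOB)
variance explained, OOB permutation importance on a chosen error metric,
Friedman partial dependence with a dispersion band, pairwise interaction
surfaces with the remaining predictors held at their medians, forest
proximities, and proximity-weighted imputation of missing predictor values.

The public surface is scikit-learn flavoured: :class:`RegressionForest` is a
``fit``/``predict`` estimator and :class:`ProximityImputer` a transformer;
the module-level functions are thin wrappers kept for pipeline use.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import _tree

__all__ = [
    "RegressionForest",
    "ProximityImputer",
    "PartialEffect",
    "InteractionGrid",
    "grow_tree",
    "fit_forest",
    "oob_variance_explained",
    "permutation_importance",
    "partial_dependence",
    "interaction_surface",
    "proximity",
    "impute_missing",
]

_MAX_SEED = 2**31 - 1


@dataclass
class PartialEffect:
    """Partial dependence of the response on one predictor.

    ``se`` is the standard error of the per-row predictions at each grid
    value (dispersion of the profile ensemble, not a sampling CI); plots in
    the field typically show ``effect ± 2·se``.
    """

    predictor: str
    grid: np.ndarray
    effect: np.ndarray
    se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictor": self.predictor, "grid": self.grid,
             "effect": self.effect, "se": self.se}
        )


@dataclass
class InteractionGrid:
    """Predicted response over a 2-D grid of two predictors.

    All remaining predictors are held at their training medians, mirroring
    the usual "interaction plot" read-out of a regression forest.
    """

    predictors: tuple[str, str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    surface: np.ndarray  # shape (len(grid_y), len(grid_x))

    def to_frame(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {self.predictors[0]: gx.ravel(), self.predictors[1]: gy.ravel(),
             "prediction": self.surface.ravel()}
        )


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=np.float64)), list(X.columns)
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


class RegressionForest(BaseEstimator, RegressorMixin):
    """Random forest for regression with OOB machinery and proximities.

    Parameters
    ----------
    n_trees : int
        Ensemble size; 999 by default.
    mtry : int or None
        Predictors tried at each node; ``ceil(p / 3)`` (the regression
        convention) when None.
    min_leaf_size : int
        Minimum rows per leaf (default 5); trees are otherwise grown to
        purity, with no depth limit.
    bootstrap : bool
        n-out-of-n sampling with replacement per tree.  Disable (together
        with ``n_trees=1, mtry=p``) to recover a single deterministic CART
        tree.
    random_state : int or None
        Seed for bootstrap draws and per-node predictor subsampling.

    Attributes
    ----------
    feature_names_in_ : list of str
    oob_prediction_ : ndarray, OOB-aggregated prediction per training row
        (NaN for rows never out of bag).
    oob_variance_explained_ : float, ``1 - MSE_OOB / Var(y)``.
    """

    def __init__(self, n_trees: int = 999, mtry: int | None = None,
                 min_leaf_size: int = 5, bootstrap: bool = True,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf_size = min_leaf_size
        self.bootstrap = bootstrap
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, p = Xm.shape
        if y.shape[0] != n:
            raise ValueError("X and y have different lengths")
        if np.isnan(Xm).any():
            raise ValueError(
                "predictor matrix contains missing values; impute first "
                "(see ProximityImputer / impute_missing)")
        if np.isnan(y).any():
            raise ValueError("response contains missing values")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.bootstrap and n < 20:
            raise ValueError("need >= 20 rows to fit a bootstrapped forest")
        if n < 2:
            raise ValueError("need >= 2 rows")
        mtry = self.mtry if self.mtry is not None else int(np.ceil(p / 3))
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must be in [1, {p}]")

        rng = np.random.default_rng(self.random_state)
        min_leaf = int(self.min_leaf_size)

        feats, thrs, lefts, rights, values, counts = [], [], [], [], [], []
        offsets = np.zeros(self.n_trees + 1, dtype=np.int64)
        inbag = np.zeros((self.n_trees, n), dtype=bool)
        for t in range(self.n_trees):
            tree_seed = int(rng.integers(_MAX_SEED))
            if self.bootstrap:
                idx = rng.integers(n, size=n)
            else:
                idx = np.arange(n)
            inbag[t, idx] = True
            f, th, le, ri, va, co = _tree.grow_tree(
                Xm, y, np.asarray(idx, dtype=np.int64), mtry, min_leaf,
                tree_seed)
            feats.append(f); thrs.append(th); lefts.append(le)
            rights.append(ri); values.append(va); counts.append(co)
            offsets[t + 1] = offsets[t] + f.shape[0]

        self.n_features_in_ = p
        self.feature_names_in_ = names
        self.mtry_ = mtry
        self.tree_offsets_ = offsets
        self.tree_feature_ = np.concatenate(feats)
        self.tree_threshold_ = np.concatenate(thrs)
        self.tree_left_ = np.concatenate(lefts)
        self.tree_right_ = np.concatenate(rights)
        self.tree_value_ = np.concatenate(values)
        self.tree_count_ = np.concatenate(counts)
        self.inbag_ = inbag
        self.oob_ = ~inbag
        self.X_ = Xm
        self.y_ = y
        self._rng_post = np.random.default_rng(
            None if self.random_state is None else self.random_state + 10_007)

        if self.bootstrap:
            self.oob_prediction_ = self._oob_aggregate(self._per_tree(Xm))
            covered = ~np.isnan(self.oob_prediction_)
            self.n_oob_uncovered_ = int((~covered).sum())
            if self.n_oob_uncovered_:
                import warnings
                warnings.warn(
                    f"{self.n_oob_uncovered_} rows never out of bag; "
                    "excluded from OOB error", stacklevel=2)
            var = np.var(y[covered], ddof=1) if covered.sum() > 1 else np.nan
            mse = np.mean((y[covered] - self.oob_prediction_[covered]) ** 2)
            self.oob_mse_ = float(mse)
            self.oob_variance_explained_ = (
                float(1.0 - mse / var) if var > 0 else float("nan"))
        else:
            # without bootstrap there is no out-of-bag sample
            self.oob_prediction_ = np.full(n, np.nan)
            self.n_oob_uncovered_ = n
            self.oob_mse_ = float("nan")
            self.oob_variance_explained_ = float("nan")
        return self

    # -- internals ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "tree_offsets_"):
            raise RuntimeError("forest is not fitted")

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names_in_) - set(X.columns)
            if missing:
                raise ValueError(f"unknown/missing predictors: {sorted(missing)}")
            X = X[self.feature_names_in_]
        Xm, _ = _as_matrix(X)
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError("wrong number of predictors")
        return Xm

    def _per_tree(self, Xm):
        return _tree.predict_per_tree(
            self.tree_offsets_, self.tree_feature_, self.tree_threshold_,
            self.tree_left_, self.tree_right_, self.tree_value_, Xm)

    def _oob_aggregate(self, per_tree):
        oob = self.oob_
        cnt = oob.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(oob, per_tree, 0.0).sum(axis=0) / cnt
        out[cnt == 0] = np.nan
        return out

    def _leaves(self, Xm):
        return _tree.apply_forest(
            self.tree_offsets_, self.tree_feature_, self.tree_threshold_,
            self.tree_left_, self.tree_right_, Xm)

    # -- prediction & diagnostics -----------------------------------------

    def predict(self, X):
        self._check_fitted()
        Xm = self._coerce(X)
        return self._per_tree(Xm).mean(axis=0)

    def oob_variance_explained(self) -> float:
        self._check_fitted()
        return self.oob_variance_explained_

    def permutation_importance(self, metric: str = "mae", n_perm: int = 5,
                               random_state: int | None = None) -> pd.DataFrame:
        """OOB permutation importance for every predictor.

        For each predictor the column is permuted across rows, the OOB
        prediction is re-aggregated and the OOB error recomputed; importance
        is the mean (over ``n_perm`` permutations) increase over the
        baseline OOB error.  ``metric`` is ``"mae"`` (default, matching the
        usual importance read-out for this analysis) or ``"mse"``.
        """
        self._check_fitted()
        metric = metric.lower()
        if metric not in ("mae", "mse"):
            raise ValueError("metric must be 'mae' or 'mse'")

        def err(pred, mask):
            d = self.y_[mask] - pred[mask]
            return float(np.mean(np.abs(d)) if metric == "mae"
                         else np.mean(d ** 2))

        covered = ~np.isnan(self.oob_prediction_)
        baseline = err(self.oob_prediction_, covered)
        rng = (np.random.default_rng(random_state) if random_state is not None
               else self._rng_post)
        n = self.X_.shape[0]
        rows = []
        for j, name in enumerate(self.feature_names_in_):
            col = self.X_[:, j]
            if np.all(col == col[0]):
                # permuting a constant column cannot change any prediction
                rows.append((name, baseline, baseline, 0.0))
                continue
            errs = np.empty(n_perm)
            for r in range(n_perm):
                perm = rng.permutation(n)
                Xp = self.X_.copy()
                Xp[:, j] = col[perm]
                pred = self._oob_aggregate(self._per_tree(Xp))
                errs[r] = err(pred, covered & ~np.isnan(pred))
            rows.append((name, baseline, float(errs.mean()),
                         float(errs.mean() - baseline)))
        out = pd.DataFrame(rows, columns=["predictor", "baseline_error",
                                          "permuted_error", "importance"])
        out["metric"] = metric
        return out.sort_values("importance", ascending=False,
                               kind="mergesort").reset_index(drop=True)

    def partial_dependence(self, predictor: str, grid_size: int = 25,
                           grid: np.ndarray | None = None) -> PartialEffect:
        """Friedman partial dependence over the predictor's observed range."""
        self._check_fitted()
        j = self.feature_names_in_.index(predictor)
        col = self.X_[:, j]
        if grid is None:
            grid = np.linspace(col.min(), col.max(), grid_size)
        grid = np.asarray(grid, dtype=np.float64)
        n = self.X_.shape[0]
        effect = np.empty(grid.size)
        se = np.empty(grid.size)
        for k, g in enumerate(grid):
            Xg = self.X_.copy()
            Xg[:, j] = g
            preds = self._per_tree(Xg).mean(axis=0)
            effect[k] = preds.mean()
            se[k] = preds.std(ddof=1) / np.sqrt(n)
        return PartialEffect(predictor, grid, effect, se)

    def interaction_surface(self, predictor_pair: tuple[str, str],
                            grid_size: int = 20) -> InteractionGrid:
        """Joint predicted response; remaining predictors at their medians."""
        self._check_fitted()
        na, nb = predictor_pair
        ja = self.feature_names_in_.index(na)
        jb = self.feature_names_in_.index(nb)
        ga = np.linspace(self.X_[:, ja].min(), self.X_[:, ja].max(), grid_size)
        gb = np.linspace(self.X_[:, jb].min(), self.X_[:, jb].max(), grid_size)
        base = np.median(self.X_, axis=0)
        cells = np.tile(base, (grid_size * grid_size, 1))
        gx, gy = np.meshgrid(ga, gb)
        cells[:, ja] = gx.ravel()
        cells[:, jb] = gy.ravel()
        surface = self._per_tree(np.ascontiguousarray(cells)).mean(axis=0)
        return InteractionGrid((na, nb), ga, gb,
                               surface.reshape(grid_size, grid_size))

    def proximity(self, X=None) -> np.ndarray:
        """Symmetric matrix of shared-terminal-node fractions."""
        self._check_fitted()
        Xm = self.X_ if X is None else self._coerce(X)
        return _tree.proximity_from_leaves(self._leaves(Xm))


class ProximityImputer(BaseEstimator, TransformerMixin):
    """Iterative proximity-weighted imputation of missing predictor values.

    Missing cells are first filled with column medians; each iteration fits a
    :class:`RegressionForest` on the current completion (the response is part
    of the fit, as in response-aware forest imputation), derives the
    proximity matrix, and replaces every missing cell with the
    proximity-weighted average of the column's observed values.

    Attributes
    ----------
    iterations_ : list of ndarray
        The completed matrix after each stage; ``iterations_[0]`` is the
        median fill.
    deltas_ : list of float
        RMS change of the imputed cells between successive iterations.
    """

    def __init__(self, n_iter: int = 5, n_trees: int = 300,
                 mtry: int | None = None, min_leaf_size: int = 5,
                 random_state: int | None = None):
        self.n_iter = n_iter
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf_size = min_leaf_size
        self.random_state = random_state

    def fit_transform(self, X, y, **fit_params):
        is_frame = isinstance(X, pd.DataFrame)
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        mask = np.isnan(Xm)
        frac = mask.mean(axis=0)
        if (frac == 1.0).any():
            bad = [names[j] for j in np.where(frac == 1.0)[0]]
            raise ValueError(f"columns entirely missing: {bad}")
        if (frac > 0.20).any():
            bad = [names[j] for j in np.where(frac > 0.20)[0]]
            raise ValueError(f"more than 20% missing in columns {bad}")

        filled = Xm.copy()
        medians = np.nanmedian(Xm, axis=0)
        for j in range(Xm.shape[1]):
            filled[mask[:, j], j] = medians[j]
        self.iterations_ = [filled.copy()]
        self.deltas_ = []

        if not mask.any():
            self.feature_names_in_ = names
            return X if is_frame else filled

        rng = np.random.default_rng(self.random_state)
        for _ in range(self.n_iter):
            forest = RegressionForest(
                n_trees=self.n_trees, mtry=self.mtry,
                min_leaf_size=self.min_leaf_size,
                random_state=int(rng.integers(_MAX_SEED)))
            forest.fit(filled, y)
            prox = forest.proximity()
            new = filled.copy()
            for j in range(Xm.shape[1]):
                miss = mask[:, j]
                if not miss.any():
                    continue
                obs = ~miss
                w = prox[np.ix_(miss, obs)]
                wsum = w.sum(axis=1)
                vals = w @ Xm[obs, j]
                ok = wsum > 0
                upd = np.where(ok, vals / np.where(ok, wsum, 1.0),
                               medians[j])
                new[miss, j] = upd
            self.deltas_.append(
                float(np.sqrt(np.mean((new[mask] - filled[mask]) ** 2))))
            filled = new
            self.iterations_.append(filled.copy())

        self.feature_names_in_ = names
        if is_frame:
            return pd.DataFrame(filled, index=X.index, columns=names)
        return filled


# -- thin functional wrappers (pipeline surface) ---------------------------

def grow_tree(table, response, mtry=None, min_leaf_size=5, random_state=0):
    """Grow one deterministic CART tree on the full table (no bootstrap)."""
    forest = RegressionForest(n_trees=1, mtry=mtry,
                              min_leaf_size=min_leaf_size, bootstrap=False,
                              random_state=random_state)
    forest.fit(table, response)
    return forest


def fit_forest(features, response, n_trees=999, mtry=None, min_leaf_size=5,
               seed=None):
    return RegressionForest(n_trees=n_trees, mtry=mtry,
                            min_leaf_size=min_leaf_size,
                            random_state=seed).fit(features, response)


def oob_variance_explained(forest: RegressionForest) -> float:
    return forest.oob_variance_explained()


def permutation_importance(forest, metric="mae", n_perm=5, seed=None):
    return forest.permutation_importance(metric=metric, n_perm=n_perm,
                                         random_state=seed)


def partial_dependence(forest, predictor, grid_size=25):
    return forest.partial_dependence(predictor, grid_size=grid_size)


def interaction_surface(forest, predictor_pair, grid_size=20):
    return forest.interaction_surface(predictor_pair, grid_size=grid_size)


def proximity(forest, rows=None):
    return forest.proximity(rows)


def impute_missing(features, response, n_iter=5, seed=None, n_trees=300):
    """Complete a predictor table; returns (completed table, imputer)."""
    imp = ProximityImputer(n_iter=n_iter, n_trees=n_trees, random_state=seed)
    completed = imp.fit_transform(features, response)
    return completed, imp
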