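"""Stacked ensemble carbon-flux model.

Three base learners — bagged regression trees, gradient-boosted trees and a
kernel margin (support-vector) regressor — are combined by a meta learner, a
bagged-trees model fitted on the base learners' out-of-fold predictions, the
standard stacking discipline that keeps the meta learner from overfitting
its inputs.  The meta learner is a quantile regression forest: it retains
its leaf response distributions, so the 5th/95th conditional quantiles give
a 90% prediction interval per pixel.

Organisation follows the Model/Results convention: build a
:class:`CarbonFluxModel` from a design matrix and learner specs, call
``fit()``, and work with the returned :class:`CarbonFluxResults` (CV
metrics, map prediction, permutation importance, ``summary()``).

Case weights (inverse measurement variance, mean 1) enter every base
learner as observation weights; the meta learner combines already-weighted
base predictions and is fit unweighted.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .covariates import CovariateStack, DesignMatrix, pixel_design
from .evaluation import CVResult, MetricSet, compute_metrics, kfold_split
from .raster import RasterGrid

logger = logging.getLogger(__name__)

FAMILIES = ("bagged_trees", "gradient_boosted_trees", "kernel_margin")

#: data-source category → supercategory used in the importance roll-up
SUPERCATEGORY = {
    "CCI": "global-AGB-maps",
    "Flux": "global-AGB-maps",
    "AGB": "global-AGB-maps",
    "CONUS": "global-AGB-maps",
    "envi": "other-dynamic",
    "LC": "other-dynamic",
    "mgmt": "static",
    "topo": "static",
    "climate": "static",
}


@dataclass
class LearnerSpec:
    """One base learner family with its hyperparameter grid."""

    family: str
    hyper_grid: dict[str, list]
    tuned_values: dict | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if not self.hyper_grid:
            raise ValueError("hyper_grid must be non-empty")

    def grid_combinations(self):
        keys = list(self.hyper_grid)
        for values in itertools.product(*(self.hyper_grid[k] for k in keys)):
            yield dict(zip(keys, values))

    @property
    def params(self) -> dict:
        if self.tuned_values is not None:
            return self.tuned_values
        combos = list(self.grid_combinations())
        if len(combos) == 1:
            return combos[0]
        raise ValueError(f"{self.family}: grid not tuned yet")


def default_learner_specs(fast: bool = False) -> list[LearnerSpec]:
    """Published-style small grids for the three base families.

    ``fast=True`` collapses each grid to one sensible combination with fewer
    trees, for demos and quick runs.
    """
    if fast:
        return [
            LearnerSpec("bagged_trees",
                        {"n_estimators": [100], "max_features": ["sqrt"]}),
            LearnerSpec("gradient_boosted_trees",
                        {"n_estimators": [150], "max_depth": [6],
                         "learning_rate": [0.1]}),
            LearnerSpec("kernel_margin", {"C": [10.0], "gamma_mult": [1.0]}),
        ]
    return [
        LearnerSpec(
            "bagged_trees",
            {"n_estimators": [250, 500], "max_features": ["sqrt", 0.33]},
        ),
        LearnerSpec(
            "gradient_boosted_trees",
            {"n_estimators": [250], "max_depth": [3, 6, 9],
             "learning_rate": [0.05, 0.1]},
        ),
        LearnerSpec(
            "kernel_margin",
            {"C": [1.0, 10.0], "gamma_mult": [0.5, 1.0, 2.0]},
        ),
    ]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _ScaledSVR:
    """Support-vector regressor with internal standardisation and a
    median-heuristic RBF width scaled by ``gamma_mult``."""

    def __init__(self, C=1.0, gamma_mult=1.0, epsilon=0.1):
        self.C, self.gamma_mult, self.epsilon = C, gamma_mult, epsilon

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        sub = Xs[:: max(1, len(Xs) // 400)]  # deterministic thinning
        d2 = pdist(sub, "sqeuclidean")
        med = np.median(d2[d2 > 0]) if (d2 > 0).any() else 1.0
        gamma = self.gamma_mult / med
        self.svr_ = SVR(C=self.C, gamma=gamma, epsilon=self.epsilon)
        self.svr_.fit(Xs, y, sample_weight=sample_weight)
        return self

    def predict(self, X):
        return self.svr_.predict(self.scaler_.transform(np.asarray(X, float)))


def make_estimator(spec: LearnerSpec, params: dict, seed: int = 0):
    if spec.family == "bagged_trees":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if spec.family == "gradient_boosted_trees":
        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="hist",
            verbosity=0, **params,
        )
    return _ScaledSVR(**params)


def _fit(est, X, y, w):
    est.fit(np.asarray(X, float), np.asarray(y, float), sample_weight=w)
    return est


# ---------------------------------------------------------------------------
# quantile regression forest
# ---------------------------------------------------------------------------

def _concat_ranges(starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Concatenate arange(starts[i], starts[i]+sizes[i]) vectorised."""
    total = int(sizes.sum())
    if total == 0:
        return np.empty(0, dtype=int)
    out = np.ones(total, dtype=int)
    ends = np.cumsum(sizes)
    out[0] = starts[0]
    out[ends[:-1]] = starts[1:] - (starts[:-1] + sizes[:-1] - 1)
    return np.cumsum(out)


class QuantileRegressionForest:
    """Random forest that retains leaf response distributions.

    Conditional quantiles follow Meinshausen's estimator: a query point's
    response distribution is the training responses weighted by the mean
    over trees of (co-leaf indicator / leaf size).
    """

    def __init__(self, n_estimators=200, min_samples_leaf=5, max_features=1.0,
                 random_state=0):
        self.rf = RandomForestRegressor(
            n_estimators=n_estimators,
            min_samples_leaf=min_samples_leaf,
            max_features=max_features,
            random_state=random_state,
            n_jobs=1,
        )

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.rf.fit(X, y, sample_weight=sample_weight)
        order_y = np.argsort(y, kind="stable")
        self.y_sorted_ = y[order_y]
        rank = np.empty(len(y), dtype=int)
        rank[order_y] = np.arange(len(y))
        leaves = self.rf.apply(X)
        self.trees_ = []
        for t in range(leaves.shape[1]):
            order = np.argsort(leaves[:, t], kind="stable")
            lv = leaves[order, t]
            uniq, starts = np.unique(lv, return_index=True)
            self.trees_.append((uniq, starts.astype(int), rank[order]))
        self.n_train_ = len(y)
        return self

    def predict(self, X):
        return self.rf.predict(np.asarray(X, dtype=float))

    def predict_quantiles(self, X, levels=(0.05, 0.95), chunk_size=2000):
        X = np.asarray(X, dtype=float)
        levels = np.atleast_1d(np.asarray(levels, dtype=float))
        if ((levels <= 0) | (levels >= 1)).any():
            raise ValueError("quantile levels must lie strictly inside (0, 1)")
        n_trees = len(self.trees_)
        out = np.empty((len(X), len(levels)))
        for lo in range(0, len(X), chunk_size):
            Xc = X[lo : lo + chunk_size]
            leaves_q = self.rf.apply(Xc)
            W = np.zeros((len(Xc), self.n_train_))
            rows_base = np.arange(len(Xc))
            for t, (uniq, starts, cols_sorted) in enumerate(self.trees_):
                pos = np.searchsorted(uniq, leaves_q[:, t])
                ends = np.append(starts[1:], self.n_train_)
                sizes = ends[pos] - starts[pos]
                rows = np.repeat(rows_base, sizes)
                cols = cols_sorted[_concat_ranges(starts[pos], sizes)]
                np.add.at(W, (rows, cols),
                          1.0 / (n_trees * np.repeat(sizes, sizes)))
            cdf = np.cumsum(W, axis=1)
            cdf /= cdf[:, -1:]
            for j, q in enumerate(levels):
                idx = np.argmax(cdf >= q - 1e-12, axis=1)
                out[lo : lo + len(Xc), j] = self.y_sorted_[idx]
        return out


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def tune_base_learner(spec: LearnerSpec, design: DesignMatrix, k: int = 5,
                      seed: int = 0) -> LearnerSpec:
    """Grid search: every combination scored by k-fold CV RMSE.

    Fitting is case-weighted, scoring unweighted; the argmin combination is
    kept, ties broken by first-in-grid order; failed fits score +inf.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = kfold_split(len(design), k, seed)
    X = design.X.to_numpy(float)
    y = design.response
    w = design.weights
    best_combo, best_rmse = None, np.inf
    for combo in spec.grid_combinations():
        fold_rmse = []
        try:
            for f in range(k):
                tr, te = folds != f, folds == f
                est = make_estimator(spec, combo, seed=seed)
                _fit(est, X[tr], y[tr], w[tr])
                pred = est.predict(X[te])
                fold_rmse.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
            rmse = float(np.mean(fold_rmse))
        except Exception:  # noqa: BLE001 — a failing combination scores +inf
            logger.exception("tune_base_learner: combination %s failed", combo)
            rmse = np.inf
        if rmse < best_rmse:
            best_combo, best_rmse = combo, rmse
    if best_combo is None:
        raise RuntimeError(f"no grid combination of {spec.family} could be fit")
    return replace(spec, tuned_values=best_combo)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class EnsemblePrediction:
    """Flux map with 90% prediction interval and derived SD layer."""

    mean_flux: RasterGrid
    q05: RasterGrid
    q95: RasterGrid
    sd_flux: RasterGrid


@dataclass
class ImportanceTable:
    """Permutation importance per covariate (0–100, max-normalised)."""

    per_covariate: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_covariate.items(), key=lambda kv: -kv[1]),
            columns=["covariate", "importance"],
        )


def aggregate_importance(table: ImportanceTable, category_tags: dict[str, str]):
    """Category and supercategory shares (each summing to 1) of importance."""
    per_cat: dict[str, float] = {}
    for name, score in table.per_covariate.items():
        if name not in category_tags:
            raise ValueError(f"covariate {name!r} has no category tag")
        per_cat[category_tags[name]] = per_cat.get(category_tags[name], 0.0) + score
    total = sum(per_cat.values())
    if total > 0:
        per_cat = {c: v / total for c, v in per_cat.items()}
    per_super: dict[str, float] = {}
    for cat, share in per_cat.items():
        sup = SUPERCATEGORY.get(cat)
        if sup is None:
            raise ValueError(f"category {cat!r} has no supercategory")
        per_super[sup] = per_super.get(sup, 0.0) + share
    return per_cat, per_super


class CarbonFluxModel:
    """Stacked ensemble of three base learners with a QRF meta learner.

    Parameters
    ----------
    design : DesignMatrix
        Plot-level covariates, response (Mg C ha^-1) and case weights.
    specs : list of LearnerSpec
        The three base learner families; tuned or single-combination grids.
    k : int
        Number of CV folds (one random partition serves base OOF
        generation, meta training and evaluation, nested so meta inputs
        stay out-of-fold).
    seed : int
        Master seed for fold assignment and learner randomness.
    """

    def __init__(self, design: DesignMatrix, specs=None, k: int = 5,
                 seed: int = 0, meta_params: dict | None = None):
        if specs is None:
            specs = default_learner_specs(fast=True)
        if len(specs) != 3:
            raise ValueError("the ensemble uses exactly three base learners")
        if len(design) < 2 * k:
            raise ValueError(f"need at least {2 * k} plots for {k}-fold stacking")
        self.design = design
        self.specs = list(specs)
        self.k = k
        self.seed = seed
        self.meta_params = meta_params or {}

    def tune(self) -> "CarbonFluxModel":
        """Grid-search every base learner in place."""
        self.specs = [
            tune_base_learner(s, self.design, self.k, self.seed)
            for s in self.specs
        ]
        return self

    def fit(self) -> "CarbonFluxResults":
        design = self.design
        X = design.X.to_numpy(float)
        y = design.response
        w = design.weights
        n = len(design)
        folds = kfold_split(n, self.k, self.seed)

        oof = np.empty((n, 3))
        base_fold_fits: list[list] = []
        for f in range(self.k):
            tr, te = folds != f, folds == f
            fits = []
            for b, spec in enumerate(self.specs):
                est = make_estimator(spec, spec.params, seed=self.seed)
                _fit(est, X[tr], y[tr], w[tr])
                oof[te, b] = est.predict(X[te])
                fits.append(est)
            base_fold_fits.append(fits)

        # deployment base learners: refit on all data
        deployed = [
            _fit(make_estimator(s, s.params, seed=self.seed), X, y, w)
            for s in self.specs
        ]

        # meta learner on the full OOF matrix (deployment).  The meta is fit
        # unweighted: its inputs already reflect the case weights through the
        # weighted base fits, and weighting the combiner again double-counts
        # the preference and shrinks the effective stacking sample.
        meta = QuantileRegressionForest(
            random_state=self.seed, **self.meta_params
        ).fit(oof, y)

        # evaluation: meta refit without each fold, scored on it
        cv_pred = np.empty(n)
        fold_metas = []
        per_fold: list[MetricSet] = []
        for f in range(self.k):
            tr, te = folds != f, folds == f
            meta_f = QuantileRegressionForest(
                random_state=self.seed, **self.meta_params
            ).fit(oof[tr], y[tr])
            cv_pred[te] = meta_f.predict(oof[te])
            fold_metas.append(meta_f)
            per_fold.append(compute_metrics(y[te], cv_pred[te]))

        return CarbonFluxResults(
            model=self,
            folds=folds,
            oof_base=oof,
            base_fold_fits=base_fold_fits,
            deployed_base=deployed,
            meta=meta,
            fold_metas=fold_metas,
            cv_pred=cv_pred,
            cv_result=CVResult(per_fold),
        )


@dataclass
class CarbonFluxResults:
    """Fitted ensemble: learners, CV diagnostics, map prediction, importance."""

    model: CarbonFluxModel
    folds: np.ndarray
    oof_base: np.ndarray
    base_fold_fits: list
    deployed_base: list
    meta: QuantileRegressionForest
    fold_metas: list
    cv_pred: np.ndarray
    cv_result: CVResult

    # -- map prediction -----------------------------------------------------
    def _base_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([est.predict(X) for est in self.deployed_base])

    def predict_flux(self, stack: CovariateStack) -> EnsemblePrediction:
        """Predict mean flux and the (5th, 95th) quantile maps per pixel."""
        return self.predict(stack, levels=(0.05, 0.95))

    def predict(self, stack: CovariateStack,
                levels=(0.05, 0.95)) -> EnsemblePrediction:
        from .uncertainty import sd_from_interval

        Xpix, mask, rr, cc = pixel_design(stack, self.model.design)
        Z = self._base_matrix(Xpix.to_numpy(float))
        mean = self.meta.predict(Z)
        qq = self.meta.predict_quantiles(Z, levels=levels)
        grid = stack.grid

        def to_raster(values, name):
            data = np.full(grid.shape, grid.nodata, dtype=float)
            data[rr, cc] = values
            return grid.like(data, name=name)

        mean_r = to_raster(mean, "flux_mean")
        q05_r = to_raster(qq[:, 0], "flux_q05")
        q95_r = to_raster(qq[:, -1], "flux_q95")
        sd_r = sd_from_interval(q05_r, q95_r).sd
        return EnsemblePrediction(mean_flux=mean_r, q05=q05_r, q95=q95_r,
                                  sd_flux=sd_r)

    def predict_quantiles(self, stack: CovariateStack, levels=(0.05, 0.95)):
        pred = self.predict(stack, levels=levels)
        return pred.q05, pred.q95

    # -- importance ---------------------------------------------------------
    def base_to_meta_importance(self, seed: int | None = None) -> np.ndarray:
        """Permutation ΔRMSE of each base-prediction column through the
        per-fold meta learners, averaged over folds and normalised."""
        seed = self.model.seed if seed is None else seed
        y = self.model.design.response
        delta = np.zeros(3)
        for f, meta_f in enumerate(self.fold_metas):
            te = self.folds == f
            Z = self.oof_base[te]
            base_rmse = np.sqrt(np.mean((y[te] - meta_f.predict(Z)) ** 2))
            for b in range(3):
                rng = np.random.default_rng((seed, f, b, 7))
                Zp = Z.copy()
                Zp[:, b] = rng.permutation(Zp[:, b])
                rmse = np.sqrt(np.mean((y[te] - meta_f.predict(Zp)) ** 2))
                delta[b] += (rmse - base_rmse) / len(self.fold_metas)
        delta = np.clip(delta, 0.0, None)
        if delta.sum() == 0:
            delta = np.ones(3)
        return delta / delta.sum()

    def permutation_importance(self, n_repeats: int = 1,
                               seed: int | None = None) -> ImportanceTable:
        """Permutation importance per covariate, 0–100 with max = 100.

        For each base learner and CV fold, each covariate (its one-hot block
        jointly) is shuffled in the held-out fold and the RMSE increase
        recorded, then averaged over folds.  The final score is the average
        over base learners weighted by their own importance to the meta
        learner.
        """
        seed = self.model.seed if seed is None else seed
        design = self.model.design
        X = design.X
        y = design.response
        groups = design.column_groups
        col_idx = {c: i for i, c in enumerate(X.columns)}
        Xv = X.to_numpy(float)

        imp = {g: np.zeros(3) for g in groups}
        for f in range(self.model.k):
            te = self.folds == f
            Xte, yte = Xv[te], y[te]
            for b in range(3):
                est = self.base_fold_fits[f][b]
                base_rmse = np.sqrt(np.mean((yte - est.predict(Xte)) ** 2))
                for g, cols in groups.items():
                    ci = [col_idx[c] for c in cols]
                    gid = zlib.crc32(g.encode()) % 2**16
                    deltas = []
                    for rep in range(n_repeats):
                        rng = np.random.default_rng((seed, f, b, gid, rep))
                        Xp = Xte.copy()
                        perm = rng.permutation(len(Xte))
                        Xp[:, ci] = Xp[perm][:, ci]
                        rmse = np.sqrt(np.mean((yte - est.predict(Xp)) ** 2))
                        deltas.append(rmse - base_rmse)
                    imp[g][b] += np.mean(deltas) / self.model.k

        w = self.base_to_meta_importance(seed=seed)
        scores = {g: float(np.clip(v, 0, None) @ w) for g, v in imp.items()}
        top = max(scores.values()) if scores else 0.0
        if top > 0:
            scores = {g: 100.0 * s / top for g, s in scores.items()}
        return ImportanceTable(per_covariate=scores)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cv = self.cv_result
        lines = [
            "Stacked carbon-flux ensemble (3 base learners + QRF meta learner)",
            f"  n plots: {len(self.model.design)}   folds: {self.model.k}"
            f"   seed: {self.model.seed}",
            "  base learners:",
        ]
        for spec in self.model.specs:
            lines.append(f"    {spec.family}: {spec.params}")
        lines += [
            "  five-fold cross-validation (mean ± SD across folds):",
            f"    RMSE  {cv.mean('rmse'):8.3f} ± {cv.sd('rmse'):.3f}  Mg C/ha",
            f"    ME    {cv.mean('me'):8.3f} ± {cv.sd('me'):.3f}  Mg C/ha",
            f"    R2    {cv.mean('r2'):8.3f} ± {cv.sd('r2'):.3f}",
        ]
        return "\n".join(lines)
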