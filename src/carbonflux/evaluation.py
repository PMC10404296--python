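"""Cross-validation metrics: RMSE, mean error and R².

Five-fold random cross-validation with three accuracy metrics, reported as
mean ± SD across folds::

    RMSE = sqrt( Σ (z − ẑ)² / n )
    ME   = Σ (z − ẑ) / n            (observed minus predicted)
    R²   = 1 − Σ (z − ẑ)² / Σ (z − z̄)²

R² uses the fold-local observation mean; metrics are unweighted (case
weights affect fitting only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MetricSet:
    rmse: float
    me: float
    r2: float
    n: int


@dataclass
class CVResult:
    """Per-fold metrics with unweighted mean and SD across folds."""

    per_fold: list[MetricSet]

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.per_fold], dtype=float)

    def mean(self, attr: str) -> float:
        return float(np.nanmean(self._vals(attr)))

    def sd(self, attr: str) -> float:
        return float(np.nanstd(self._vals(attr), ddof=1))

    @property
    def n_total(self) -> int:
        return int(sum(m.n for m in self.per_fold))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "rmse": m.rmse, "me": m.me, "r2": m.r2, "n": m.n}
            for i, m in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)

    def summary_row(self, label: str = "ensemble") -> pd.DataFrame:
        """One row in the accuracy-table format: metric mean ± SD."""
        return pd.DataFrame(
            [
                {
                    "scenario": label,
                    "rmse": self.mean("rmse"),
                    "rmse_sd": self.sd("rmse"),
                    "me": self.mean("me"),
                    "me_sd": self.sd("me"),
                    "r2": self.mean("r2"),
                    "r2_sd": self.sd("r2"),
                    "n": self.n_total,
                }
            ]
        )


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition into k folds with sizes differing by at most 1."""
    if n < k:
        raise ValueError(f"cannot split {n} observations into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def compute_metrics(observed, predicted) -> MetricSet:
    """RMSE, ME and R² of predictions against observations."""
    z = np.asarray(observed, dtype=float)
    zhat = np.asarray(predicted, dtype=float)
    if z.shape != zhat.shape:
        raise ValueError("observed and predicted lengths differ")
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = z - zhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    me = float(np.mean(resid))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("observed values have zero variance; R² undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return MetricSet(rmse=rmse, me=me, r2=r2, n=n)


def cross_validate(design, specs=None, k: int = 5, seed: int = 0) -> CVResult:
    """Five-fold CV of the stacked ensemble (refit per fold, nested
    base/meta discipline).  Convenience wrapper around the model object."""
    from .ensemble import CarbonFluxModel, default_learner_specs

    specs = specs or default_learner_specs()
    model = CarbonFluxModel(design, specs=specs, k=k, seed=seed)
    return model.fit().cv_result
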