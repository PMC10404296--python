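"""Feature-space coverage: where is the map unsupported by the sample?

Machine-learning flux maps extrapolate wherever a pixel's covariate vector
lies far from every reference plot in feature space.  This module computes a
dissimilarity index (DI) per pixel — the importance-weighted, standardised
Euclidean distance to the nearest training plot, normalised by the mean
pairwise distance among plots — and flags pixels beyond a threshold derived
from the cross-validated training DI distribution as under-sampled.

Only continuous covariates enter the metric (Euclidean distance on one-hot
codes would dominate it); each is standardised by its training mean/SD and
scaled by its normalised importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .covariates import CovariateStack, DesignMatrix
from .evaluation import kfold_split
from .raster import RasterGrid


@dataclass
class CoverageResult:
    dissimilarity: RasterGrid
    threshold: float
    undersampled_mask: RasterGrid
    fraction_total: float
    fraction_by_class: dict[str, float]


def _weighted_space(design: DesignMatrix, importance: dict[str, float]):
    """Continuous covariate names, training means/SDs and weight factors."""
    names = [
        g for g, cols in design.column_groups.items()
        if cols == [g]  # continuous covariates map 1:1 to a column
    ]
    if not names:
        raise ValueError("no continuous covariates available for dissimilarity")
    missing = [n for n in names if n not in importance]
    if missing:
        raise ValueError(f"importance missing for covariates: {missing}")
    imp = np.array([importance[n] for n in names], dtype=float)
    if (imp < 0).any():
        raise ValueError("importance values must be non-negative")
    if imp.sum() == 0:
        imp = np.ones(len(names))
    wts = imp / imp.sum()
    Xt = design.X[names].to_numpy(float)
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    sd[sd == 0] = 1.0
    return names, mu, sd, wts


def _transform(values: np.ndarray, mu, sd, wts) -> np.ndarray:
    return (values - mu) / sd * wts


def compute_dissimilarity(
    stack: CovariateStack, design: DesignMatrix, importance: dict[str, float]
) -> RasterGrid:
    """Dissimilarity index raster.

    DI(pixel) = (distance to nearest training plot in the weighted,
    standardised continuous-covariate space) / (mean pairwise distance among
    training plots).  Zero at cells holding a training plot.
    """
    if len(design) < 2:
        raise ValueError("need at least 2 training plots for dissimilarity")
    names, mu, sd, wts = _weighted_space(design, importance)
    train = _transform(design.X[names].to_numpy(float), mu, sd, wts)
    mean_pair = float(pdist(train).mean())
    if mean_pair == 0:
        raise ValueError("all training plots identical in feature space")

    grid = stack.grid
    mask = np.ones(grid.shape, dtype=bool)
    for n in names:
        mask &= stack.layers[n].valid_mask()
    rr, cc = np.nonzero(mask)
    pix = np.column_stack(
        [stack.layers[n].data[rr, cc].astype(float) for n in names]
    )
    dist, _ = cKDTree(train).query(_transform(pix, mu, sd, wts), k=1)
    data = np.full(grid.shape, grid.nodata, dtype=float)
    data[rr, cc] = dist / mean_pair
    return grid.like(data, name="dissimilarity")


def coverage_threshold(
    design: DesignMatrix,
    importance: dict[str, float],
    k: int = 5,
    seed: int = 0,
) -> float:
    """Under-sampling threshold from cross-validated training DI values.

    Each plot's DI to its nearest neighbour outside its own CV fold is
    computed; the threshold is Q3 + 1.5×IQR of those values (the standard
    outlier fence).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    names, mu, sd, wts = _weighted_space(design, importance)
    train = _transform(design.X[names].to_numpy(float), mu, sd, wts)
    pair = pdist(train)
    mean_pair = float(pair.mean())
    if mean_pair == 0:
        import warnings

        warnings.warn("all training plots identical; threshold degenerates to 0")
        return 0.0
    folds = kfold_split(len(design), k, seed)
    di = np.empty(len(design))
    for f in range(k):
        te = folds == f
        tree = cKDTree(train[~te])
        dist, _ = tree.query(train[te], k=1)
        di[te] = dist / mean_pair
    q1, q3 = np.percentile(di, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def undersampled_report(
    dissimilarity: RasterGrid,
    threshold: float,
    unseea_map: RasterGrid,
    class_labels=None,
):
    """Fractions of valid (vegetated) pixels above the DI threshold.

    Returns (fraction_total, fraction_by_class); classes with no pixels are
    reported as NaN (undefined), not 0.
    """
    dissimilarity.require_aligned(unseea_map, "UNSEEA map")
    valid = dissimilarity.valid_mask() & unseea_map.valid_mask()
    mask = valid & (dissimilarity.data > threshold)
    total_valid = int(valid.sum())
    fraction_total = float(mask.sum() / total_valid) if total_valid else float("nan")
    codes = np.unique(unseea_map.data[unseea_map.valid_mask()])
    by_class: dict[str, float] = {}
    for code in codes:
        label = (
            class_labels[int(code)]
            if class_labels is not None
            else str(int(code))
        )
        sel = valid & (unseea_map.data == code)
        n = int(sel.sum())
        by_class[label] = float(mask[sel].sum() / n) if n else float("nan")
    return fraction_total, by_class


def compute_coverage(
    stack: CovariateStack,
    design: DesignMatrix,
    importance: dict[str, float],
    unseea_map: RasterGrid,
    class_labels=None,
    k: int = 5,
    seed: int = 0,
) -> CoverageResult:
    """End-to-end coverage screening: DI raster, threshold, report."""
    di = compute_dissimilarity(stack, design, importance)
    thr = coverage_threshold(design, importance, k=k, seed=seed)
    mask_data = np.where(
        di.valid_mask(), (di.data > thr).astype(np.uint8), 255
    )
    mask = di.like(mask_data.astype(np.uint8), name="undersampled", nodata=255)
    frac_total, by_class = undersampled_report(di, thr, unseea_map, class_labels)
    return CoverageResult(
        dissimilarity=di,
        threshold=thr,
        undersampled_mask=mask,
        fraction_total=frac_total,
        fraction_by_class=by_class,
    )
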