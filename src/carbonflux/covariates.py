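"""Covariate stack: GLCM textures, collinearity screening, plot extraction.

The design matrix of the flux models is assembled here.  Texture layers
summarise local variability of the biomass-change inputs through gray-level
co-occurrence matrices (GLCM); a Pearson screen on a random pixel sample
removes near-duplicate layers; plot extraction performs point-in-cell lookup
with one-hot expansion of categorical layers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid
from .reference import ReferenceSet

logger = logging.getLogger(__name__)

#: covariate data-source categories used for importance roll-ups
CATEGORIES = ("CCI", "Flux", "AGB", "CONUS", "envi", "LC", "mgmt", "topo", "climate")

#: GLCM co-occurrence offsets, pooled symmetric (0°, 90°, 45°, 135°)
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class CovariateStack:
    """Aligned named raster layers with kind and category tags."""

    layers: dict[str, RasterGrid]
    kind_tags: dict[str, str]
    category_tags: dict[str, str]

    def __post_init__(self) -> None:
        names = list(self.layers)
        if not names:
            raise ValueError("empty covariate stack")
        first = self.layers[names[0]]
        for n in names[1:]:
            first.require_aligned(self.layers[n], f"layer {n!r}")
        for n in names:
            if n not in self.kind_tags or n not in self.category_tags:
                raise ValueError(f"layer {n!r} missing kind or category tag")
            if self.kind_tags[n] not in ("continuous", "categorical"):
                raise ValueError(f"bad kind tag for {n!r}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if self.kind_tags[n] == "continuous"]

    def categorical_names(self) -> list[str]:
        return [n for n in self.layers if self.kind_tags[n] == "categorical"]

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def add(self, grid: RasterGrid, kind: str, category: str, name=None) -> None:
        name = name or grid.name
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        self.grid.require_aligned(grid, f"layer {name!r}")
        self.layers[name] = grid
        self.kind_tags[name] = kind
        self.category_tags[name] = category

    def subset(self, names) -> "CovariateStack":
        return CovariateStack(
            {n: self.layers[n] for n in names},
            {n: self.kind_tags[n] for n in names},
            {n: self.category_tags[n] for n in names},
        )

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer (complete cases)."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for grid in self.layers.values():
            mask &= grid.valid_mask()
        return mask

    @classmethod
    def from_scenario(cls, scenario, glcm_window: int = 3,
                      glcm_levels: int = 32, textures_of=None) -> "CovariateStack":
        """Stack emulating the national covariate table from a synthetic scenario.

        Continuous covariates are spread over the biomass-product and
        environmental categories; the land-cover pair enters categorically.
        Texture layers are derived from the layers named in ``textures_of``
        (default: the first covariate, standing in for the biomass-change
        product).
        """
        cats = ["CCI", "Flux", "AGB", "envi", "topo", "climate"]
        layers, kinds, tags = {}, {}, {}
        for i, (name, grid) in enumerate(scenario.covariates.items()):
            layers[name] = grid
            kinds[name] = "continuous"
            tags[name] = cats[i % len(cats)]
        stack = cls(layers, kinds, tags)
        stack.add(scenario.landcover_2010, "categorical", "LC", "landcover_2010")
        stack.add(scenario.landcover_2018, "categorical", "LC", "landcover_2018")
        for src in (textures_of or [next(iter(scenario.covariates))]):
            stack.add_glcm(src, window_cells=glcm_window, gray_levels=glcm_levels)
        return stack

    def add_glcm(self, source: str, window_cells: int = 3,
                 gray_levels: int = 32) -> None:
        """Append the four GLCM texture layers of ``source``."""
        tex = compute_glcm_textures(
            self.layers[source], window_cells=window_cells, gray_levels=gray_levels
        )
        cat = self.category_tags[source]
        for stat, grid in tex.items():
            self.add(grid, "continuous", cat, f"{stat}_{source}")


# ---------------------------------------------------------------------------
# GLCM textures
# ---------------------------------------------------------------------------

def quantize_layer(layer: RasterGrid, gray_levels: int) -> np.ndarray:
    """Equal-width quantization over the layer's global finite range."""
    vals = layer.data.astype(float)
    valid = layer.valid_mask()
    finite = vals[valid]
    lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 0.0)
    if hi > lo:
        q = np.floor((vals - lo) / (hi - lo) * gray_levels).astype(int)
        q = np.clip(q, 0, gray_levels - 1)
    else:
        q = np.zeros(vals.shape, dtype=int)  # constant layer: single level
    return q


def _integral(f: np.ndarray) -> np.ndarray:
    s = np.zeros((f.shape[0] + 1, f.shape[1] + 1))
    s[1:, 1:] = f.cumsum(0).cumsum(1)
    return s


def _rect_sums(f: np.ndarray, r0, r1, c0, c1) -> np.ndarray:
    """Sums of f over rows [r0+k, r1+k] × cols [c0+m, c1+m] for all valid
    window centres; r0..c1 are offsets relative to the centre."""
    s = _integral(f)
    rows, cols = f.shape
    h = max(-r0, r1)
    w = max(-c0, c1)
    # centre ranges are chosen by the caller via slicing; compute full map
    rr = np.arange(rows)
    cc = np.arange(cols)
    out = np.full((rows, cols), np.nan)
    rlo, rhi = -r0, rows - 1 - r1
    clo, chi = -c0, cols - 1 - c1
    if rhi < rlo or chi < clo:
        return out
    R = rr[rlo : rhi + 1]
    C = cc[clo : chi + 1]
    a = s[np.ix_(R + r1 + 1, C + c1 + 1)]
    b = s[np.ix_(R + r0, C + c1 + 1)]
    c_ = s[np.ix_(R + r1 + 1, C + c0)]
    d = s[np.ix_(R + r0, C + c0)]
    out[rlo : rhi + 1, clo : chi + 1] = a - b - c_ + d
    return out


def compute_glcm_textures(
    layer: RasterGrid, window_cells: int = 3, gray_levels: int = 32
) -> dict[str, RasterGrid]:
    """GLCM mean, variance, homogeneity and contrast in a moving window.

    Per centre pixel the window values are quantized into ``gray_levels``
    equal-width bins over the layer's global finite range, and the symmetric,
    normalised co-occurrence matrix P is accumulated over the four offsets
    (0,1), (1,0), (1,1), (1,−1) pooled.  The four statistics are::

        texMean     = Σ_ij i·P(i,j)
        texVar      = Σ_ij (i − texMean)²·P(i,j)
        texHomo     = Σ_ij P(i,j) / (1 + (i−j)²)
        texContrast = Σ_ij (i−j)²·P(i,j)

    Because P is symmetric and pooled, each statistic is a plain average over
    co-occurring level pairs, which allows an exact windowed-sum evaluation
    (no per-window matrix is materialised).  Centres whose window is
    incomplete (grid border or any nodata cell) are nodata.
    """
    if window_cells % 2 != 1 or window_cells < 1:
        raise ValueError("window_cells must be odd and positive")
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    q = quantize_layer(layer, gray_levels).astype(float)
    valid = layer.valid_mask()
    rows, cols = q.shape
    h = window_cells // 2

    S1 = np.zeros((rows, cols))   # Σ (a+b) over pairs
    S2 = np.zeros((rows, cols))   # Σ (a²+b²)
    CO = np.zeros((rows, cols))   # Σ (a−b)²
    HO = np.zeros((rows, cols))   # Σ 1/(1+(a−b)²)
    n_pairs = 0.0
    for dy, dx in GLCM_OFFSETS:
        # pair field at "first pixel" positions p with p+offset in grid
        a = np.full((rows, cols), np.nan)
        sl_r = slice(max(0, -dy), rows - max(0, dy))
        sl_c = slice(max(0, -dx), cols - max(0, dx))
        sl_r2 = slice(max(0, dy), rows - max(0, -dy))
        sl_c2 = slice(max(0, dx), cols - max(0, -dx))
        pa = q[sl_r, sl_c]
        pb = q[sl_r2, sl_c2]

        def put(values: np.ndarray) -> np.ndarray:
            f = np.zeros((rows, cols))
            f[sl_r, sl_c] = values
            return f

        # rectangle of first-pixel positions inside the window
        r0, r1 = -h + max(0, -dy), h - max(0, dy)
        c0, c1 = -h + max(0, -dx), h - max(0, dx)
        S1 += np.nan_to_num(_rect_sums(put(pa + pb), r0, r1, c0, c1))
        S2 += np.nan_to_num(_rect_sums(put(pa**2 + pb**2), r0, r1, c0, c1))
        d2 = (pa - pb) ** 2
        CO += np.nan_to_num(_rect_sums(put(d2), r0, r1, c0, c1))
        HO += np.nan_to_num(_rect_sums(put(1.0 / (1.0 + d2)), r0, r1, c0, c1))
        n_pairs += (window_cells - abs(dy)) * (window_cells - abs(dx))

    n_endpoints = 2.0 * n_pairs
    mean = S1 / n_endpoints
    var = np.maximum(S2 / n_endpoints - mean**2, 0.0)
    contrast = CO / n_pairs
    homo = HO / n_pairs

    # validity: full window inside grid and free of nodata
    ok = np.zeros((rows, cols), dtype=bool)
    win_valid = _rect_sums(valid.astype(float), -h, h, -h, h)
    interior = ~np.isnan(win_valid)
    ok[interior] = win_valid[interior] == window_cells**2

    out = {}
    for stat, arr in (
        ("texMean", mean), ("texVar", var), ("texHomo", homo),
        ("texContrast", contrast),
    ):
        data = np.where(ok, arr, layer.nodata)
        out[stat] = layer.like(data.astype(float), name=stat)
    return out


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def screen_collinearity(
    stack: CovariateStack,
    n_sample: int = 5000,
    r_threshold: float = 0.8,
    always_keep=None,
    seed: int = 0,
) -> list[str]:
    """Drop near-duplicate layers by pairwise Pearson correlation.

    Correlations are computed on a random sample of complete-case pixels
    (default 5000).  While any pair exceeds ``|r| > r_threshold``, one member
    is dropped: texture mean/variance layers first (they duplicate other
    texture properties), otherwise the member with the larger mean absolute
    correlation against the remaining layers.  The land-cover pair (category
    "LC") is kept unconditionally by default so a dynamic input survives.
    Returns the retained layer names in stack order.
    """
    if always_keep is None:
        always_keep = {n for n, c in stack.category_tags.items() if c == "LC"}
    always_keep = set(always_keep)
    names = stack.names
    mask = stack.valid_mask()
    idx = np.flatnonzero(mask.ravel())
    if n_sample < len(idx):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=n_sample, replace=False))
    else:
        logger.warning(
            "screen_collinearity: only %d valid pixels (< n_sample=%d); using all",
            len(idx), n_sample,
        )
    sample = np.column_stack(
        [stack.layers[n].data.ravel()[idx].astype(float) for n in names]
    )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sample, rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    np.fill_diagonal(corr, 0.0)

    active = list(range(len(names)))

    def droppable(i: int) -> bool:
        return names[i] not in always_keep

    def is_tex_dup(i: int) -> bool:
        return names[i].startswith(("texMean", "texVar"))

    while True:
        best, best_r = None, r_threshold
        for i, j in itertools.combinations(active, 2):
            if corr[i, j] > best_r and (droppable(i) or droppable(j)):
                best, best_r = (i, j), corr[i, j]
        if best is None:
            break
        i, j = best
        candidates = [k for k in best if droppable(k)]
        if len(candidates) == 1:
            drop = candidates[0]
        else:
            tex = [k for k in candidates if is_tex_dup(k)]
            if len(tex) == 1:
                drop = tex[0]
            else:
                pool = tex or candidates
                rest = [k for k in active if k not in best]
                mean_r = {
                    k: corr[k, rest].mean() if rest else corr[i, j] for k in pool
                }
                drop = max(pool, key=lambda k: (mean_r[k], names[k]))
        active.remove(drop)
        logger.info("screen_collinearity: dropped %s (|r|=%.3f with %s)",
                    names[drop], best_r, names[i if drop == j else j])
    return [names[k] for k in active]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Model-ready covariate matrix at plot locations.

    ``X`` holds one row per retained plot (categorical layers one-hot
    expanded), ``response`` the observed carbon flux, ``weights`` the case
    weights, ``coords`` the plot coordinates.  ``column_groups`` maps each
    source covariate to its expanded column names so permutation importance
    can shuffle a covariate's indicator block jointly.
    """

    X: pd.DataFrame
    response: np.ndarray
    weights: np.ndarray
    coords: np.ndarray
    column_groups: dict[str, list[str]]
    cat_levels: dict[str, list[int]] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.response) == len(self.weights) == len(self.coords) == n):
            raise ValueError("design matrix row counts disagree")
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing cells")

    def __len__(self) -> int:
        return len(self.X)


def _expand_columns(stack: CovariateStack, names):
    """Column plan: continuous 1:1, categorical one-hot over observed codes."""
    groups: dict[str, list[str]] = {}
    cat_levels: dict[str, list[int]] = {}
    for n in names:
        if stack.kind_tags[n] == "continuous":
            groups[n] = [n]
        else:
            grid = stack.layers[n]
            codes = np.unique(grid.data[grid.valid_mask()]).astype(int)
            cat_levels[n] = codes.tolist()
            groups[n] = [f"{n}={c}" for c in codes]
    return groups, cat_levels


def _matrix_from_values(stack, names, values, groups, cat_levels) -> pd.DataFrame:
    cols = {}
    for n in names:
        v = values[n]
        if stack.kind_tags[n] == "continuous":
            cols[n] = v.astype(float)
        else:
            for c in cat_levels[n]:
                cols[f"{n}={c}"] = (v.astype(int) == c).astype(float)
    return pd.DataFrame(cols)


def extract_at_plots(
    stack: CovariateStack, refset: ReferenceSet, retained=None
) -> DesignMatrix:
    """Point-in-cell covariate lookup at plot locations.

    Plots falling on a nodata cell of any retained layer are dropped and the
    count logged; plots outside the grid bounds raise.
    """
    names = list(retained) if retained is not None else stack.names
    grid = stack.grid
    df = refset.df
    rr, cc = [], []
    inside = []
    for x, y in zip(df["x"], df["y"]):
        try:
            r, c = grid.cell_at(x, y)
        except IndexError:
            inside.append(False)
            rr.append(0)
            cc.append(0)
        else:
            inside.append(True)
            rr.append(r)
            cc.append(c)
    inside = np.array(inside)
    if not inside.any():
        raise ValueError("all plots fall outside the covariate grid")
    rr, cc = np.array(rr), np.array(cc)

    valid = inside.copy()
    for n in names:
        vm = stack.layers[n].valid_mask()
        valid &= np.where(inside, vm[rr, cc], False)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("extract_at_plots: dropped %d plots (nodata/outside)", n_dropped)
    if not valid.any():
        raise ValueError("no plots on valid covariate cells")

    rr, cc = rr[valid], cc[valid]
    groups, cat_levels = _expand_columns(stack, names)
    values = {n: stack.layers[n].data[rr, cc] for n in names}
    X = _matrix_from_values(stack, names, values, groups, cat_levels)
    sub = df.loc[valid]
    weights = (
        sub["weight"].to_numpy(float)
        if "weight" in sub.columns
        else np.ones(len(sub))
    )
    return DesignMatrix(
        X=X,
        response=sub["flux_obs"].to_numpy(float),
        weights=weights,
        coords=sub[["x", "y"]].to_numpy(float),
        column_groups=groups,
        cat_levels=cat_levels,
        n_dropped=n_dropped,
    )


def pixel_design(stack: CovariateStack, template: DesignMatrix):
    """Design matrix over all complete-case pixels, matching ``template``'s
    columns.  Returns (X, valid_mask, rows, cols of each row)."""
    names = list(template.column_groups)
    missing = [n for n in names if n not in stack.layers]
    if missing:
        raise ValueError(f"missing covariate layers: {missing}")
    mask = np.ones(stack.grid.shape, dtype=bool)
    for n in names:
        mask &= stack.layers[n].valid_mask()
    rr, cc = np.nonzero(mask)
    values = {n: stack.layers[n].data[rr, cc] for n in names}
    X = _matrix_from_values(stack, names, values, template.column_groups,
                            template.cat_levels)
    X = X.reindex(columns=template.X.columns, fill_value=0.0)
    return X, mask, rr, cc
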