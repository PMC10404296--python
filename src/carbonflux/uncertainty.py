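"""From prediction intervals to class-level SDs.

Per-pixel uncertainty starts as a 90% prediction interval (5th/95th
quantiles).  The interval is converted to a Gaussian-equivalent SD layer;
the spatial correlation of standardized residuals at plot locations is
modelled by an empirical variogram with a fitted exponential (or spherical)
model; and per-pixel SDs are aggregated to a per-class variance by summing
pairwise error covariances

    sigma_ij = rho(h_ij) * SD_i * SD_j,

with rho the correlogram implied by the fitted variogram, truncated beyond
its effective range (which makes an exact windowed summation feasible).  In
independent mode rho is identically zero off-diagonal — the appropriate
choice when fitted ranges are short relative to class extents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform

from .raster import RasterGrid
from .reference import ReferenceSet

logger = logging.getLogger(__name__)

#: half-width of a central 90% interval in Gaussian SD units
Z90 = 1.6448536269514722


@dataclass
class SDLayer:
    sd: RasterGrid
    role: str = "flux"  # flux | opening
    mode: str = "corrected"


def sd_from_interval(q05: RasterGrid, q95: RasterGrid,
                     mode: str = "corrected") -> SDLayer:
    """Gaussian-equivalent SD of a 90% prediction interval.

    corrected (default): SD = (q95 − q05) / (2 × 1.645), the Gaussian
    identity for a central 90% interval.  literal: SD = ((q95 − q05)/2) ×
    1.64, the multiplicative form sometimes used in reports; it inflates SD
    by ≈2.70× relative to the identity and is kept only for comparability.
    """
    if mode not in ("corrected", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    q05.require_aligned(q95, "quantile layer")
    lo, hi = q05.data, q95.data
    valid = q05.valid_mask() & q95.valid_mask()
    bad = valid & (lo > hi)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"q05 > q95 at pixel ({r}, {c})")
    width = hi - lo
    if mode == "corrected":
        sd = width / (2.0 * Z90)
    else:
        sd = width / 2.0 * 1.64
    data = np.where(valid, sd, q05.nodata)
    return SDLayer(sd=q05.like(data, name=f"sd_{mode}"), mode=mode)


def standardized_residuals(prediction, refset: ReferenceSet) -> pd.DataFrame:
    """(x, y, residual) table of (z − ẑ)/SD_flux at plot cells.

    Plots on nodata prediction cells are dropped and logged.
    """
    mean, sd = prediction.mean_flux, prediction.sd_flux
    rows = []
    n_dropped = 0
    for rec in refset.df.itertuples():
        try:
            r, c = mean.cell_at(rec.x, rec.y)
        except IndexError:
            n_dropped += 1
            continue
        if not (mean.valid_mask()[r, c] and sd.valid_mask()[r, c]):
            n_dropped += 1
            continue
        s = sd.data[r, c]
        if s <= 0:
            raise ValueError(f"non-positive SD at plot {rec.plot_id}")
        rows.append((rec.x, rec.y, (rec.flux_obs - mean.data[r, c]) / s))
    if n_dropped:
        logger.info("standardized_residuals: dropped %d plots on nodata", n_dropped)
    return pd.DataFrame(rows, columns=["x", "y", "residual"])


def empirical_variogram(points: pd.DataFrame, n_lags: int = 15,
                        max_dist_m: float | None = None,
                        min_points: int = 30) -> pd.DataFrame:
    """Matheron semivariance estimator in equal-width distance bins.

    gamma(h) = (1 / 2N(h)) * sum over pairs of (r_i − r_j)²; zero-distance
    pairs are excluded, empty bins omitted.  Returns columns
    (lag, semivariance, n_pairs) with lag the bin centre.
    """
    if len(points) < min_points:
        raise ValueError(f"need at least {min_points} points for a variogram")
    xy = points[["x", "y"]].to_numpy(float)
    r = points["residual"].to_numpy(float)
    d = pdist(xy)
    g = pdist(r[:, None], "sqeuclidean") / 2.0
    if max_dist_m is None:
        span = np.sqrt(
            (xy[:, 0].max() - xy[:, 0].min()) ** 2
            + (xy[:, 1].max() - xy[:, 1].min()) ** 2
        )
        max_dist_m = span / 2.0
    keep = (d > 0) & (d <= max_dist_m)
    d, g = d[keep], g[keep]
    edges = np.linspace(0, max_dist_m, n_lags + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    rows = []
    for b in range(n_lags):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2.0, float(g[sel].mean()), n))
    return pd.DataFrame(rows, columns=["lag", "semivariance", "n_pairs"])


@dataclass
class CorrelogramModel:
    """Fitted variogram model and the correlation function it implies."""

    family: str
    nugget: float
    partial_sill: float
    range_param: float
    empirical: pd.DataFrame | None = None

    @property
    def total_sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def effective_range_m(self) -> float:
        """Distance where correlation ~ dies out (3× range parameter for the
        exponential family, the range itself for the spherical)."""
        if self.family == "exponential":
            return 3.0 * self.range_param
        return self.range_param

    def _corr(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            c = np.exp(-h / self.range_param) if self.range_param > 0 else 0.0 * h
        elif self.family == "spherical":
            a = self.range_param
            u = np.clip(h / a, 0, 1) if a > 0 else np.ones_like(h)
            c = 1 - 1.5 * u + 0.5 * u**3
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return c

    def semivariance(self, h):
        h = np.asarray(h, dtype=float)
        gamma = self.nugget + self.partial_sill * (1.0 - self._corr(h))
        return np.where(h == 0, 0.0, gamma)

    def rho(self, h):
        """Error correlation: rho(0)=1, rho = partial_sill·c(h)/total sill
        for h>0, truncated to 0 beyond the effective range."""
        h = np.asarray(h, dtype=float)
        if self.total_sill == 0:
            return np.where(h == 0, 1.0, 0.0)
        r = self.partial_sill * self._corr(h) / self.total_sill
        r = np.where(h > self.effective_range_m, 0.0, r)
        return np.where(h == 0, 1.0, r)


def pure_nugget(sill: float = 1.0) -> CorrelogramModel:
    return CorrelogramModel("exponential", nugget=sill, partial_sill=0.0,
                            range_param=1.0)


def fit_correlogram(empirical: pd.DataFrame,
                    family: str = "exponential") -> CorrelogramModel:
    """Pair-count-weighted least-squares fit of (nugget, partial sill, range).

    Falls back to a pure-nugget model (rho ≡ 0) with a warning if the
    optimiser fails to converge.
    """
    if family not in ("exponential", "spherical"):
        raise ValueError(f"unknown family {family!r}")
    emp = empirical.dropna()
    if len(emp) < 4:
        raise ValueError("need at least 4 non-empty variogram bins")
    h = emp["lag"].to_numpy(float)
    g = emp["semivariance"].to_numpy(float)
    n = emp["n_pairs"].to_numpy(float)

    def model(hh, nug, psill, rng_):
        m = CorrelogramModel(family, nug, psill, rng_)
        return m.nugget + m.partial_sill * (1.0 - m._corr(hh))

    gmax = g.max() if g.max() > 0 else 1.0
    p0 = [max(g[0] * 0.5, 1e-6), max(gmax - g[0] * 0.5, 1e-6), h.max() / 4.0]
    try:
        popt, _ = curve_fit(
            model, h, g, p0=p0,
            sigma=1.0 / np.sqrt(n), absolute_sigma=False,
            # ranges beyond the observed lag span are not identifiable
            bounds=([0, 0, 1e-9], [np.inf, np.inf, float(h.max())]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        warnings.warn("variogram fit did not converge; using pure-nugget model")
        return pure_nugget(float(np.average(g, weights=n)))
    m = CorrelogramModel(family, *map(float, popt), empirical=emp)
    if m.effective_range_m < h.min():
        # structure below the first lag is indistinguishable from nugget
        m = CorrelogramModel(family, nugget=m.total_sill, partial_sill=0.0,
                             range_param=m.range_param, empirical=emp)
    return m


@dataclass
class ClassVariance:
    """Aggregated carbon variance of one accounting class, in Tg C units."""

    unseea_class: str
    n_pixels: int
    variance_TgC2: float
    mode: str  # independent | correlated

    @property
    def sd_TgC(self) -> float:
        return float(np.sqrt(self.variance_TgC2))


MG_PER_TG = 1e6


def aggregate_class_variance(
    sd_layer: SDLayer,
    class_mask: np.ndarray,
    correlogram: CorrelogramModel | None = None,
    cell_area_ha: float = 1.0,
    mode: str = "independent",
    unseea_class: str = "",
) -> ClassVariance:
    """Class variance by pairwise covariance summation.

    Pixel SDs (Mg C ha^-1) are converted to per-pixel Mg C via the cell
    area, then var = ΣΣ rho(h_ij)·SD_i·SD_j.  Correlated mode exploits the
    correlogram's finite effective range with a windowed shift-and-multiply
    summation (exact, O(pixels × offsets)); independent mode reduces to
    Σ SD_i².  The result is returned in Tg² C.
    """
    if mode not in ("independent", "correlated"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "correlated" and correlogram is None:
        raise ValueError("correlated mode requires a fitted correlogram")
    grid = sd_layer.sd
    mask = np.asarray(class_mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("class mask shape does not match SD layer")
    mask = mask & grid.valid_mask()
    sd_mg = np.where(mask, grid.data * cell_area_ha, 0.0)  # Mg C per pixel
    n_pix = int(mask.sum())

    var = float(np.sum(sd_mg**2))
    if mode == "correlated" and n_pix:
        cell = grid.cell_size_m
        rows, cols = grid.shape
        max_cells = int(np.floor(correlogram.effective_range_m / cell))
        max_dy = min(max_cells, rows - 1)
        max_dx = min(max_cells, cols - 1)
        for dy in range(0, max_dy + 1):
            for dx in range(-max_dx, max_dx + 1):
                if dy == 0 and dx <= 0:
                    continue  # half-plane; (0,0) handled by the Σ sd² term
                h = cell * np.hypot(dy, dx)
                if h > correlogram.effective_range_m:
                    continue
                rho = float(correlogram.rho(h))
                if rho == 0.0:
                    continue
                a = sd_mg[dy:, max(0, dx):cols + min(0, dx)]
                b = sd_mg[: rows - dy, max(0, -dx):cols + min(0, -dx)]
                var += 2.0 * rho * float(np.sum(a * b))

    return ClassVariance(
        unseea_class=unseea_class,
        n_pixels=n_pix,
        variance_TgC2=var / MG_PER_TG**2,
        mode=mode,
    )


def aggregate_class_variance_bruteforce(
    sd_layer: SDLayer,
    class_mask: np.ndarray,
    correlogram: CorrelogramModel,
    cell_area_ha: float = 1.0,
    unseea_class: str = "",
) -> ClassVariance:
    """Literal O(n²) double-loop covariance summation (reference oracle)."""
    grid = sd_layer.sd
    mask = np.asarray(class_mask, dtype=bool) & grid.valid_mask()
    rr, cc = np.nonzero(mask)
    sd_mg = grid.data[rr, cc] * cell_area_ha
    x, y = grid.coords_of(rr, cc)
    pts = np.column_stack([x, y])
    h = squareform(pdist(pts))
    rho = correlogram.rho(h)
    var = float(sd_mg @ rho @ sd_mg)
    return ClassVariance(
        unseea_class=unseea_class,
        n_pixels=len(rr),
        variance_TgC2=var / MG_PER_TG**2,
        mode="correlated",
    )


def closing_stock_variance(opening: ClassVariance,
                           flux: ClassVariance) -> ClassVariance:
    """Closing variance = opening + flux variance (independent errors)."""
    if opening.unseea_class != flux.unseea_class:
        raise ValueError(
            f"class mismatch: {opening.unseea_class!r} vs {flux.unseea_class!r}"
        )
    if opening.mode != flux.mode:
        raise ValueError("opening and flux variances use different modes")
    return ClassVariance(
        unseea_class=opening.unseea_class,
        n_pixels=opening.n_pixels,
        variance_TgC2=opening.variance_TgC2 + flux.variance_TgC2,
        mode=opening.mode,
    )
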