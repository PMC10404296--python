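"""Synthetic landscapes with known truth.

The national analysis this package implements runs on inputs that cannot be
bundled (country inventories, LiDAR footprint maps, global biomass products).
This module generates stand-ins with the statistical structure the pipeline
assumes — spatially autocorrelated covariates, a land-cover pair with
forest→non-forest transitions, a true flux surface that is a known function
of the covariates plus correlated noise, and plot samples under uniform,
systematic or clustered designs with heteroscedastic measurement error — so
every downstream stage is testable against a known truth.

Random fields are realised by Gaussian-kernel smoothing of white noise,
re-standardised to unit variance; the requested correlation length is the
kernel SD.  Only the autocorrelation structure matters downstream, so this
dependency-light construction suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import NODATA_INT, RasterGrid
from .reference import ReferenceSet

#: UNSEEA level-2 vegetated classes used by the carbon accounts
UNSEEA_CLASSES = (
    "broadleaved",
    "coniferous",
    "mixed",
    "mangroves",
    "other_woody",
    "plantation",
)

#: labels counted as forest for transition/attribution logic
FOREST_LABELS = frozenset(
    {"broadleaved", "coniferous", "mixed", "mangroves", "plantation"}
)

DEFAULT_CLASSES = ("broadleaved", "coniferous", "mixed", "other_woody")


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study landscape.

    Defaults describe the reference condition used across the test-bed: a
    moderately autocorrelated six-covariate landscape whose flux signal has
    roughly twice the SD of its correlated noise, sampled by a few hundred
    plots with 20% relative measurement error.
    """

    grid_shape: tuple[int, int] = (100, 100)
    cell_size_m: float = 100.0
    n_covariates: int = 6
    covariate_corr_length_m: float = 1000.0
    flux_coefficients: tuple[float, ...] | None = None
    noise_sd: float = 5.0
    noise_corr_length_m: float = 500.0
    landcover_classes: tuple[str, ...] = DEFAULT_CLASSES
    transition_fraction: float = 0.1
    sampling_design: str = "uniform"
    n_plots: int = 400
    cluster_count: int = 8
    cluster_radius_m: float = 1000.0
    measurement_cv: float = 0.2
    plantation_fraction: float = 0.1
    opening_mean: float = 60.0
    opening_rel_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if not 0 <= self.transition_fraction <= 1:
            raise ValueError("transition_fraction must be in [0, 1]")
        if self.n_plots > rows * cols:
            raise ValueError("n_plots exceeds number of grid cells")
        for name in ("covariate_corr_length_m", "noise_corr_length_m",
                     "cluster_radius_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.sampling_design not in ("uniform", "systematic", "clustered"):
            raise ValueError(f"unknown sampling design {self.sampling_design!r}")
        if self.flux_coefficients is None:
            # decaying coefficients: few strong drivers, several weak ones
            self.flux_coefficients = tuple(
                round(8.0 * 0.6**i, 4) for i in range(self.n_covariates)
            )
        if len(self.flux_coefficients) != self.n_covariates:
            raise ValueError("flux_coefficients length must equal n_covariates")
        unknown = set(self.landcover_classes) - set(UNSEEA_CLASSES)
        if unknown:
            raise ValueError(f"unknown UNSEEA class labels: {sorted(unknown)}")


@dataclass
class SyntheticScenario:
    """A realised landscape plus the truth record needed to audit it."""

    spec: ScenarioSpec
    covariates: dict[str, RasterGrid]
    true_flux: RasterGrid
    landcover_2010: RasterGrid
    landcover_2018: RasterGrid
    plantation_mask: RasterGrid
    opening_stock: RasterGrid
    opening_sd: RasterGrid
    plots: ReferenceSet
    truth_record: dict = field(default_factory=dict)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self.spec.landcover_classes)


def _correlated_field(rng: np.random.Generator, shape, corr_cells: float) -> np.ndarray:
    """Stationary unit-variance Gaussian field with kernel-SD corr_cells."""
    white = rng.standard_normal(shape)
    if corr_cells > 0:
        f = ndimage.gaussian_filter(white, sigma=corr_cells, mode="wrap")
    else:
        f = white
    f = f - f.mean()
    sd = f.std()
    if sd > 0:
        f = f / sd
    return f


def generate_covariate_fields(spec: ScenarioSpec) -> dict[str, RasterGrid]:
    """Standardised stationary random fields, one per covariate.

    Each field has mean 0 / SD 1 and approximate correlation length
    ``covariate_corr_length_m`` (Gaussian-kernel SD).  Deterministic given
    the scenario seed.
    """
    if spec.covariate_corr_length_m < 0:
        raise ValueError("correlation length must be >= 0")
    rng = np.random.default_rng(spec.seed)
    corr_cells = spec.covariate_corr_length_m / spec.cell_size_m
    out: dict[str, RasterGrid] = {}
    for i in range(spec.n_covariates):
        name = f"cov{i:02d}"
        arr = _correlated_field(rng, spec.grid_shape, corr_cells)
        out[name] = RasterGrid(arr, cell_size_m=spec.cell_size_m, name=name)
    return out


def generate_true_flux(
    covariates: dict[str, RasterGrid], spec: ScenarioSpec
) -> RasterGrid:
    """True net carbon flux: linear signal plus correlated Gaussian noise.

    flux = sum_k beta_k * covariate_k + eps, with eps a stationary field of
    sample SD exactly ``noise_sd`` and correlation length
    ``noise_corr_length_m``.  Units Mg C ha^-1; losses negative.
    """
    names = list(covariates)
    if len(spec.flux_coefficients) != len(names):
        raise ValueError("coefficients length must equal number of covariates")
    first = covariates[names[0]]
    signal = np.zeros(first.shape)
    for beta, name in zip(spec.flux_coefficients, names):
        grid = covariates[name]
        if grid.shape != first.shape:
            raise ValueError(f"covariate {name} shape mismatch")
        signal = signal + beta * grid.data
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        noise = _correlated_field(
            rng, first.shape, spec.noise_corr_length_m / spec.cell_size_m
        )
        signal = signal + spec.noise_sd * noise
    return first.like(signal, name="true_flux")


def generate_landcover_pair(
    spec: ScenarioSpec, latent: RasterGrid
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """2010/2018 land-cover maps plus a plantation mask.

    The 2010 map partitions pixels among the configured classes by latent
    field quantile thresholds (equal shares).  The 2018 map equals 2010
    except that ``transition_fraction`` of forest pixels flips to the first
    non-forest class, emulating forest conversion.  The plantation mask is a
    subset of 2010 forest pixels (the highest-latent slice).
    """
    classes = list(spec.landcover_classes)
    vals = latent.data.ravel()
    qs = np.quantile(vals, np.linspace(0, 1, len(classes) + 1)[1:-1])
    codes = np.digitize(latent.data, qs).astype(np.uint8)
    lc2010 = latent.like(codes, name="landcover_2010", nodata=NODATA_INT)

    forest_codes = [i for i, c in enumerate(classes) if c in FOREST_LABELS]
    nonforest_codes = [i for i, c in enumerate(classes) if c not in FOREST_LABELS]
    forest_mask = np.isin(codes, forest_codes)
    n_forest = int(forest_mask.sum())

    codes18 = codes.copy()
    if spec.transition_fraction > 0:
        if not nonforest_codes:
            raise ValueError("no non-forest class available for transitions")
        n_flip = int(round(spec.transition_fraction * n_forest))
        if n_flip > n_forest:
            raise ValueError("transition_fraction exceeds available forest share")
        rng = np.random.default_rng(spec.seed + 2)
        forest_idx = np.flatnonzero(forest_mask.ravel())
        flip = rng.choice(forest_idx, size=n_flip, replace=False)
        flat = codes18.ravel()
        flat[flip] = nonforest_codes[0]
        codes18 = flat.reshape(codes.shape)
    lc2018 = latent.like(codes18, name="landcover_2018", nodata=NODATA_INT)

    # plantations: contiguous top-latent slice of 2010 forest
    plant = np.zeros(codes.shape, dtype=bool)
    if spec.plantation_fraction > 0 and n_forest > 0:
        thresh = np.quantile(
            latent.data[forest_mask], 1.0 - spec.plantation_fraction
        )
        plant = forest_mask & (latent.data >= thresh)
    plantation = latent.like(plant.astype(np.uint8), name="plantation_mask",
                             nodata=NODATA_INT)
    return lc2010, lc2018, plantation


def _plot_positions(spec: ScenarioSpec, rng: np.random.Generator):
    rows, cols = spec.grid_shape
    if spec.sampling_design == "uniform":
        idx = rng.choice(rows * cols, size=spec.n_plots, replace=False)
        rr, cc = np.unravel_index(idx, (rows, cols))
    elif spec.sampling_design == "systematic":
        step = max(1, int(np.floor(np.sqrt(rows * cols / spec.n_plots))))
        off = step // 2
        rr_all, cc_all = np.meshgrid(
            np.arange(off, rows, step), np.arange(off, cols, step), indexing="ij"
        )
        rr, cc = rr_all.ravel(), cc_all.ravel()
        if len(rr) < spec.n_plots:
            raise ValueError("systematic lattice too sparse for n_plots")
        rr, cc = rr[: spec.n_plots], cc[: spec.n_plots]
    else:  # clustered
        radius_cells = spec.cluster_radius_m / spec.cell_size_m
        margin = int(np.ceil(radius_cells))
        lo_r, hi_r = min(margin, rows // 2), max(rows - margin, rows // 2 + 1)
        lo_c, hi_c = min(margin, cols // 2), max(cols - margin, cols // 2 + 1)
        centers_r = rng.integers(lo_r, hi_r, size=spec.cluster_count)
        centers_c = rng.integers(lo_c, hi_c, size=spec.cluster_count)
        which = rng.integers(0, spec.cluster_count, size=spec.n_plots)
        ang = rng.uniform(0, 2 * np.pi, size=spec.n_plots)
        rad = radius_cells * np.sqrt(rng.uniform(0, 1, size=spec.n_plots))
        rr = np.clip(np.round(centers_r[which] + rad * np.sin(ang)), 0, rows - 1)
        cc = np.clip(np.round(centers_c[which] + rad * np.cos(ang)), 0, cols - 1)
        rr, cc = rr.astype(int), cc.astype(int)
    return rr, cc


def sample_plots(true_flux: RasterGrid, spec: ScenarioSpec) -> ReferenceSet:
    """Plot sample with design-driven locations and heteroscedastic error.

    Observed flux = true flux at the cell + Gaussian error with
    SD = measurement_cv × max(|true flux|, 1); the same SD squared fills the
    variance column.  Clustered designs emulate LiDAR footprints (source
    "LIDAR"); uniform and systematic emulate inventories (source "NFI").
    """
    rng = np.random.default_rng(spec.seed + 3)
    rr, cc = _plot_positions(spec, rng)
    truth = true_flux.data[rr, cc].astype(float)
    sd = spec.measurement_cv * np.maximum(np.abs(truth), 1.0)
    obs = truth + rng.standard_normal(len(truth)) * sd
    x, y = true_flux.coords_of(rr, cc)
    source = "LIDAR" if spec.sampling_design == "clustered" else "NFI"
    df = pd.DataFrame(
        {
            "plot_id": [f"P{i:05d}" for i in range(len(truth))],
            "x": x,
            "y": y,
            "flux_obs": obs,
            "flux_var": sd**2,
            "source": source,
            "forest_change_flag": False,
            "edge_flag": False,
        }
    )
    return ReferenceSet(df, design_tag=spec.sampling_design, units_note="carbon")


def generate_scenario(spec: ScenarioSpec) -> SyntheticScenario:
    """Full landscape realisation: covariates, truth, land cover, plots."""
    covariates = generate_covariate_fields(spec)
    true_flux = generate_true_flux(covariates, spec)
    first = next(iter(covariates.values()))
    # latent field for the land-cover partition, independent of the flux noise
    rng_latent = np.random.default_rng(spec.seed + 4)
    latent = first.like(
        _correlated_field(
            rng_latent, spec.grid_shape,
            spec.covariate_corr_length_m / spec.cell_size_m,
        ),
        name="latent",
    )
    lc2010, lc2018, plantation = generate_landcover_pair(spec, latent)
    plots = sample_plots(true_flux, spec)
    # opening stock: positive carbon stock surface with known relative SD
    rng_open = np.random.default_rng(spec.seed + 5)
    open_field = _correlated_field(
        rng_open, spec.grid_shape, spec.covariate_corr_length_m / spec.cell_size_m
    )
    opening = np.maximum(spec.opening_mean * (1.0 + 0.25 * open_field), 0.0)
    opening_stock = first.like(opening, name="opening_stock")
    opening_sd = first.like(spec.opening_rel_sd * opening, name="opening_sd")
    return SyntheticScenario(
        spec=spec,
        covariates=covariates,
        true_flux=true_flux,
        landcover_2010=lc2010,
        landcover_2018=lc2018,
        plantation_mask=plantation,
        opening_stock=opening_stock,
        opening_sd=opening_sd,
        plots=plots,
        truth_record={
            "flux_coefficients": tuple(spec.flux_coefficients),
            "noise_sd": spec.noise_sd,
            "noise_corr_length_m": spec.noise_corr_length_m,
            "seed": spec.seed,
        },
    )
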