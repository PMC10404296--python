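"""Reference-plot preparation.

Field plots (national forest inventory re-measurements) and LiDAR-derived
1-ha "plots" enter the pipeline as a flat table of net above-ground change
observations.  This module quality-filters them, converts biomass change to
carbon flux, attaches plot-level measurement variances, and computes the
inverse-variance case weights used by the prediction models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of the plots CSV dialect
PLOT_COLUMNS = [
    "plot_id",
    "x",
    "y",
    "flux_obs",
    "flux_var",
    "source",
    "forest_change_flag",
    "edge_flag",
]


@dataclass
class ReferenceSet:
    """Quality-flagged reference plots with flux, variance and case weight.

    ``df`` carries one row per plot with the :data:`PLOT_COLUMNS` (plus a
    ``weight`` column once computed).  ``units_note`` records whether
    ``flux_obs`` is still biomass change ("biomass") or carbon flux
    ("carbon", Mg C ha^-1).
    """

    df: pd.DataFrame
    design_tag: str = "uniform"
    units_note: str = "carbon"

    def __post_init__(self) -> None:
        missing = [c for c in PLOT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if self.df["plot_id"].duplicated().any():
            raise ValueError("plot_id values must be unique")
        if (self.df["flux_var"].to_numpy() < 0).any():
            raise ValueError("flux_var must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def weights(self) -> np.ndarray:
        if "weight" not in self.df.columns:
            raise AttributeError("case weights not computed; run compute_case_weights")
        return self.df["weight"].to_numpy()

    def to_csv(self, path) -> None:
        cols = PLOT_COLUMNS + (["weight"] if "weight" in self.df.columns else [])
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design_tag: str = "uniform", units_note: str = "carbon"):
        df = pd.read_csv(path)
        for flag in ("forest_change_flag", "edge_flag"):
            df[flag] = df[flag].astype(bool)
        return cls(df, design_tag=design_tag, units_note=units_note)


def filter_plots(refset: ReferenceSet) -> ReferenceSet:
    """Drop plots with forest-area change or LiDAR footprint-edge overlap.

    Only plots without forest area changes over the accounting period and
    without partial pixel overlap at footprint edges are retained.  Order is
    preserved; the number removed is logged.
    """
    df = refset.df
    keep = ~(df["forest_change_flag"].to_numpy() | df["edge_flag"].to_numpy())
    removed = int((~keep).sum())
    logger.info("filter_plots: removed %d of %d plots", removed, len(df))
    if not keep.any():
        raise ValueError("all plots removed by quality filters; model cannot be fit")
    return replace(refset, df=df.loc[keep].reset_index(drop=True))


def biomass_to_carbon(refset: ReferenceSet, fraction: float = 0.49) -> ReferenceSet:
    """Convert biomass change to carbon flux with a dry-biomass carbon fraction.

    flux is multiplied by ``fraction`` and variance by ``fraction**2``.
    Raises if the set is already in carbon units (double conversion).
    """
    if refset.units_note == "carbon":
        raise ValueError("reference set already in carbon units")
    if not 0 < fraction <= 1:
        raise ValueError("carbon fraction must be in (0, 1]")
    df = refset.df.copy()
    df["flux_obs"] = df["flux_obs"] * fraction
    df["flux_var"] = df["flux_var"] * fraction**2
    return replace(refset, df=df, units_note="carbon")


def estimate_plot_variance(
    refset: ReferenceSet,
    nfi_relative_sd: float = 0.2,
    floor: float = 1.0,
) -> ReferenceSet:
    """Fill measurement variances for NFI plots lacking one.

    NFI plot uncertainty is modelled as a relative SD of the observed flux
    with an absolute floor (Mg C ha^-1) so that near-zero fluxes keep a
    positive variance.  LiDAR records come with variances from their
    uncertainty layers and are passed through untouched, as are NFI records
    with a supplied (positive) variance.
    """
    if nfi_relative_sd < 0:
        raise ValueError("nfi_relative_sd must be non-negative")
    df = refset.df.copy()
    flux = df["flux_obs"].to_numpy(dtype=float)
    var = df["flux_var"].to_numpy(dtype=float)
    needs = (df["source"].to_numpy() == "NFI") & (var <= 0)
    sd = nfi_relative_sd * np.maximum(np.abs(flux), floor)
    var = np.where(needs, sd**2, var)
    df["flux_var"] = var
    return replace(refset, df=df)


def compute_case_weights(refset: ReferenceSet) -> ReferenceSet:
    """Inverse-variance case weights, normalised to mean 1.

    weight_i = (1/var_i) / mean_j(1/var_j).  Mean-1 normalisation leaves the
    effective sample size unchanged so learner defaults stay meaningful.
    """
    var = refset.df["flux_var"].to_numpy(dtype=float)
    if (var <= 0).any():
        raise ValueError(
            "zero or negative plot variance; apply estimate_plot_variance "
            "with a positive floor first"
        )
    inv = 1.0 / var
    df = refset.df.copy()
    df["weight"] = inv / inv.mean()
    return replace(refset, df=df)


def prepare(
    refset: ReferenceSet,
    carbon_fraction: float = 0.49,
    nfi_relative_sd: float = 0.2,
    variance_floor: float = 1.0,
) -> ReferenceSet:
    """Full preparation chain: filter, convert units, variance model, weights."""
    out = filter_plots(refset)
    if out.units_note == "biomass":
        out = biomass_to_carbon(out, carbon_fraction)
    out = estimate_plot_variance(out, nfi_relative_sd, variance_floor)
    return compute_case_weights(out)
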