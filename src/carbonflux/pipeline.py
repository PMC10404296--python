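"""End-to-end pipeline: simulate → prepare → covariates → fit → evaluate →
predict → coverage → aggregate → account.

One YAML config and one master seed drive the whole run; every stage seed
is derived deterministically from the master seed, so re-running an
identical config reproduces identical numeric outputs.  Stages are lazy
cached properties of :class:`PipelineRun`, so a stage command recomputes its
upstream stages in memory from the config rather than deserialising
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accounts import build_account_table, class_totals, emissions_split, \
    reclassify_landcover
from .coverage import compute_coverage
from .covariates import CovariateStack, extract_at_plots, screen_collinearity
from .ensemble import CarbonFluxModel, aggregate_importance, \
    default_learner_specs
from .reference import prepare as prepare_reference
from .synthetic import FOREST_LABELS, ScenarioSpec, generate_scenario
from .uncertainty import aggregate_class_variance, closing_stock_variance, \
    empirical_variogram, fit_correlogram, sd_from_interval, \
    standardized_residuals

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "scenario": {},
    "reference": {"carbon_fraction": 0.49, "nfi_relative_sd": 0.2,
                  "variance_floor": 1.0},
    "glcm": {"window_cells": 3, "gray_levels": 32},
    "screening": {"n_sample": 5000, "r_threshold": 0.8},
    "learners": {"fast": True, "tune": False},
    "cv": {"k": 5},
    "coverage": {"k": 5},
    "variogram": {"n_lags": 15, "family": "exponential"},
    "aggregation": {"mode": "independent", "eq4_mode": "corrected"},
    "seed": 0,
}


def load_config(path=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if key not in cfg:
                raise ValueError(f"unknown config section {key!r}")
            if isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["scenario", "screening", "model", "coverage", "importance"]
    state = np.random.SeedSequence(master).generate_state(len(names))
    return {n: int(s % 2**31) for n, s in zip(names, state)}


class PipelineRun:
    """Lazy, deterministic pipeline over one config + master seed."""

    def __init__(self, config: dict, seed: int | None = None):
        self.config = config
        self.seed = int(config.get("seed", 0) if seed is None else seed)
        self.seeds = _stage_seeds(self.seed)
        self.timings: dict[str, float] = {}

    def _timed(self, name, fn):
        t0 = time.perf_counter()
        out = fn()
        self.timings[name] = time.perf_counter() - t0
        logger.info("stage %-12s %.1f s", name, self.timings[name])
        return out

    # -- stages -------------------------------------------------------------
    @cached_property
    def scenario(self):
        spec = ScenarioSpec(**{**self.config["scenario"],
                               "seed": self.seeds["scenario"]})
        return self._timed("simulate", lambda: generate_scenario(spec))

    @cached_property
    def plots(self):
        ref = self.config["reference"]
        return self._timed(
            "prepare",
            lambda: prepare_reference(
                self.scenario.plots,
                carbon_fraction=ref["carbon_fraction"],
                nfi_relative_sd=ref["nfi_relative_sd"],
                variance_floor=ref["variance_floor"],
            ),
        )

    @cached_property
    def stack(self) -> CovariateStack:
        g = self.config["glcm"]
        return self._timed(
            "covariates",
            lambda: CovariateStack.from_scenario(
                self.scenario, glcm_window=g["window_cells"],
                glcm_levels=g["gray_levels"],
            ),
        )

    @cached_property
    def retained(self) -> list[str]:
        s = self.config["screening"]
        return self._timed(
            "screening",
            lambda: screen_collinearity(
                self.stack, n_sample=s["n_sample"],
                r_threshold=s["r_threshold"], seed=self.seeds["screening"],
            ),
        )

    @cached_property
    def design(self):
        return extract_at_plots(self.stack, self.plots, retained=self.retained)

    @cached_property
    def results(self):
        lc = self.config["learners"]
        specs = default_learner_specs(fast=lc.get("fast", True))
        k = self.config["cv"]["k"]

        def _fit():
            model = CarbonFluxModel(self.design, specs=specs, k=k,
                                    seed=self.seeds["model"])
            if lc.get("tune", False):
                model.tune()
            else:
                model.specs = [
                    s if s.tuned_values else
                    type(s)(s.family, s.hyper_grid,
                            next(iter(s.grid_combinations())))
                    for s in model.specs
                ]
            return model.fit()

        return self._timed("fit", _fit)

    @cached_property
    def prediction(self):
        return self._timed("predict",
                           lambda: self.results.predict_flux(self.stack))

    @cached_property
    def importance(self):
        return self._timed(
            "importance",
            lambda: self.results.permutation_importance(
                seed=self.seeds["importance"]),
        )

    @cached_property
    def classmap(self):
        labels = self.scenario.class_labels
        mapping = {i: lab for i, lab in enumerate(labels)}
        return reclassify_landcover(
            self.scenario.landcover_2010, self.scenario.plantation_mask,
            mapping,
            target_cell_m=self.scenario.landcover_2010.cell_size_m,
        )

    @cached_property
    def coverage(self):
        imp = {
            name: self.importance.per_covariate.get(name, 0.0)
            for name, cols in self.design.column_groups.items()
            if cols == [name]
        }
        return self._timed(
            "coverage",
            lambda: compute_coverage(
                self.stack, self.design, imp, self.classmap.classes,
                class_labels=self.classmap.labels,
                k=self.config["coverage"]["k"], seed=self.seeds["coverage"],
            ),
        )

    @cached_property
    def correlogram(self):
        v = self.config["variogram"]

        def _fit():
            resid = standardized_residuals(self.prediction, self.plots)
            emp = empirical_variogram(resid, n_lags=v["n_lags"])
            return fit_correlogram(emp, family=v["family"])

        return self._timed("variogram", _fit)

    @cached_property
    def variances(self):
        agg = self.config["aggregation"]
        mode = agg["mode"]
        corr = self.correlogram if mode == "correlated" else None
        flux_sd = sd_from_interval(self.prediction.q05, self.prediction.q95,
                                   mode=agg["eq4_mode"])
        from .uncertainty import SDLayer

        open_sd = SDLayer(sd=self.scenario.opening_sd, role="opening")
        cell_area_ha = (self.stack.grid.cell_size_m / 100.0) ** 2

        def _agg():
            out = {}
            for label in self.classmap.present_labels():
                m = self.classmap.mask_of(label)
                out[label] = {
                    "opening": aggregate_class_variance(
                        open_sd, m, corr, cell_area_ha, mode, label),
                    "flux": aggregate_class_variance(
                        flux_sd, m, corr, cell_area_ha, mode, label),
                }
                out[label]["closing"] = closing_stock_variance(
                    out[label]["opening"], out[label]["flux"])
            return out

        return self._timed("aggregate", _agg)

    @cached_property
    def account(self):
        sc = self.scenario
        cell_area_ha = (self.stack.grid.cell_size_m / 100.0) ** 2

        def _build():
            totals = class_totals(sc.opening_stock, self.prediction.mean_flux,
                                  self.classmap, cell_area_ha)
            splits = emissions_split(
                self.prediction.mean_flux, self.classmap,
                sc.landcover_2010, sc.landcover_2018,
                forest_labels_2010=FOREST_LABELS,
                class_labels_2010=sc.class_labels,
                cell_area_ha=cell_area_ha,
            )
            return build_account_table(totals, self.variances, splits)

        return self._timed("account", _build)

    # -- artifact writers ---------------------------------------------------
    def write_stage(self, stage: str, out: Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        rasters = out / "rasters"
        if stage in ("simulate", "predict", "coverage", "run-all"):
            rasters.mkdir(exist_ok=True)
        try:
            getattr(self, f"_write_{stage.replace('-', '_')}")(out, rasters)
        except AttributeError as err:
            raise ValueError(f"unknown pipeline stage {stage!r}") from err

    def _write_simulate(self, out, rasters):
        sc = self.scenario
        sc.plots.to_csv(out / "plots.csv")
        for name, grid in sc.covariates.items():
            grid.write_tiff(rasters / f"{name}.tif")
        for grid in (sc.true_flux, sc.landcover_2010, sc.landcover_2018,
                     sc.plantation_mask, sc.opening_stock, sc.opening_sd):
            grid.write_tiff(rasters / f"{grid.name}.tif")
        (out / "truth_record.json").write_text(
            json.dumps(sc.truth_record, indent=2))

    def _write_prepare(self, out, rasters):
        self.plots.to_csv(out / "plots_prepared.csv")

    def _write_fit(self, out, rasters):
        res = self.results
        pd.DataFrame(
            [{"family": s.family, **(s.tuned_values or s.params)}
             for s in res.model.specs]
        ).to_csv(out / "tuned_hyperparameters.csv", index=False)
        res.cv_result.to_frame().to_csv(out / "cv_folds.csv", index=False)
        res.cv_result.summary_row().to_csv(out / "cv_metrics.csv", index=False)
        self.importance.to_frame().to_csv(out / "importance.csv", index=False)
        cats, supers = aggregate_importance(
            self.importance,
            {g: self.stack.category_tags[g] for g in self.design.column_groups},
        )
        pd.DataFrame(sorted(cats.items()), columns=["category", "share"]).to_csv(
            out / "importance_by_category.csv", index=False)
        pd.DataFrame(sorted(supers.items()),
                     columns=["supercategory", "share"]).to_csv(
            out / "importance_by_supercategory.csv", index=False)
        pd.DataFrame({"covariate": self.retained}).to_csv(
            out / "retained_covariates.csv", index=False)
        (out / "model_summary.txt").write_text(res.summary() + "\n")

    def _write_predict(self, out, rasters):
        p = self.prediction
        for grid in (p.mean_flux, p.q05, p.q95, p.sd_flux):
            grid.write_tiff(rasters / f"{grid.name or 'layer'}.tif")

    def _write_coverage(self, out, rasters):
        cov = self.coverage
        cov.dissimilarity.write_tiff(rasters / "dissimilarity.tif")
        cov.undersampled_mask.write_tiff(rasters / "undersampled.tif")
        rows = [{"class": "TOTAL", "fraction_undersampled": cov.fraction_total}]
        rows += [{"class": c, "fraction_undersampled": f}
                 for c, f in sorted(cov.fraction_by_class.items())]
        pd.DataFrame(rows).to_csv(out / "coverage.csv", index=False)

    def _write_aggregate(self, out, rasters):
        m = self.correlogram
        if m.empirical is not None:
            m.empirical.to_csv(out / "variogram.csv", index=False)
        (out / "correlogram.json").write_text(json.dumps({
            "family": m.family, "nugget": m.nugget,
            "partial_sill": m.partial_sill, "range_param": m.range_param,
            "total_sill": m.total_sill,
            "effective_range_m": m.effective_range_m,
        }, indent=2))
        rows = []
        for label, v in self.variances.items():
            for role in ("opening", "flux", "closing"):
                cv = v[role]
                rows.append({"unseea_class": label, "role": role,
                             "mode": cv.mode, "n_pixels": cv.n_pixels,
                             "variance_TgC2": cv.variance_TgC2,
                             "sd_TgC": cv.sd_TgC})
        pd.DataFrame(rows).to_csv(out / "class_variances.csv", index=False)

    def _write_account(self, out, rasters):
        self.account.to_csv(out / "account.csv")
        (out / "account.txt").write_text(self.account.summary() + "\n")

    def _write_run_all(self, out, rasters):
        for stage in ("simulate", "prepare", "fit", "predict", "coverage",
                      "aggregate", "account"):
            getattr(self, f"_write_{stage}")(out, rasters)
        self._write_manifest(out)

    def _write_manifest(self, out: Path) -> None:
        canon = yaml.safe_dump(self.config, sort_keys=True)
        manifest = {
            "package_version": __version__,
            "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
            "master_seed": self.seed,
            "stage_seeds": self.seeds,
            "scenario_spec": {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in asdict(self.scenario.spec).items()},
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> PipelineRun:
    """Execute every stage and write all artifacts; returns the run object."""
    run = PipelineRun(config, seed=seed)
    run.write_stage("run-all", Path(out_dir))
    return run
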