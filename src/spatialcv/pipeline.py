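"""End-to-end experiment orchestration: the full validation audit.

``run_experiment`` ties the stages together — scenario simulation or CSV
ingest, pixel filtering, covariate engineering, variogram diagnostics,
random and spatial K-fold CV, the B-LOO radius sweep, and the final
skill-vs-distance report — and writes every artifact plus a JSON manifest
from which the run can be reproduced exactly.

Seeding: a master seed fans out to per-stage seeds through fixed offsets
(``STAGE_SEED_OFFSETS``), so toggling one stage never perturbs another's
randomness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import derive_climate_columns
from .crossval import DEFAULT_BLOO_RADII, BlooCurve, CVResult, bloo_cv, run_kfold_cv
from .filters import FilterConfig, apply_filters
from .folds import random_kfold_split, spatial_kfold_split
from .models import ModelSpec, predict_coordinates
from .synthetic import SampleSet, ScenarioConfig, _json_default, build_scenario
from .variogram import empirical_variogram, residual_variogram

logger = logging.getLogger("spatialcv")

STAGE_SEED_OFFSETS = {
    "scenario": 0,
    "random_folds": 1,
    "bloo": 2,
    "models": 3,
    "geopredict": 4,
}

#: Numeric output precision (significant digits) for byte-stable CSVs.
CSV_FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of one audit experiment."""

    scenario: ScenarioConfig | None = None
    input_csv: str | None = None
    qc_columns: tuple[str, ...] = ()
    filters: FilterConfig | None = None
    derive_climate: bool = False
    random_k: int = 10
    clustering_height_km: float = 150.0
    bloo_radii_km: tuple[float, ...] = DEFAULT_BLOO_RADII
    bloo_n_test: int = 100
    bloo_n_reps: int = 10
    run_bloo: bool = True
    model_specs: tuple[ModelSpec, ...] = (
        ModelSpec("RF_RSE"), ModelSpec("RF_XY"), ModelSpec("NULL"),
    )
    variogram_bin_width_km: float = 10.0
    variogram_max_lag_km: float | None = None
    master_seed: int = 0

    def __post_init__(self):
        if (self.scenario is None) == (self.input_csv is None):
            raise ValueError("exactly one of scenario or input_csv must be set")
        if not self.model_specs:
            raise ValueError("at least one model spec required")


def stage_seed(master_seed: int, stage: str) -> int:
    return master_seed * len(STAGE_SEED_OFFSETS) + STAGE_SEED_OFFSETS[stage]


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


@dataclass
class ExperimentResult:
    """In-memory bundle of everything an experiment produced."""

    sample_set: SampleSet
    filter_report: object | None
    response_variogram: object
    kfold_results: dict[str, dict[str, CVResult]]
    bloo_curves: dict[str, BlooCurve]
    report: pd.DataFrame | None
    manifest: dict


def _load_input(config: ExperimentConfig) -> SampleSet:
    if config.scenario is not None:
        return build_scenario(config.scenario)
    return SampleSet.from_csv(config.input_csv, qc_columns=config.qc_columns)


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the audit workflow; optionally write all artifacts to disk.

    Stage order: ingest/simulate → filters → covariate engineering →
    variogram diagnostics → random and spatial K-fold CV (per model) →
    residual variograms → B-LOO sweep (per model) → skill report.
    Any stage failure propagates with the stage name prepended.
    """
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            if out is not None:
                (out / "failure.log").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    sample_set = stage("input", _load_input, config)
    logger.info("loaded %d samples", len(sample_set))

    filter_report = None
    if config.filters is not None:
        sample_set, filter_report = stage("filters", apply_filters,
                                          sample_set, config.filters)
        logger.info("filters kept %d samples", len(sample_set))

    if config.derive_climate:
        frame = stage("engineering", derive_climate_columns, sample_set.frame)
        sample_set = SampleSet(frame, qc_columns=sample_set.qc_columns,
                               provenance=sample_set.provenance,
                               allow_duplicate_coordinates=True)

    response_vg = stage(
        "variogram", empirical_variogram, sample_set.response,
        sample_set.coords, config.variogram_bin_width_km,
        config.variogram_max_lag_km,
    )

    random_folds = stage("random_folds", random_kfold_split, len(sample_set),
                         config.random_k,
                         stage_seed(config.master_seed, "random_folds"))
    spatial_folds = stage("spatial_folds", spatial_kfold_split,
                          sample_set.coords, config.clustering_height_km)
    logger.info("spatial clustering produced K=%d folds", spatial_folds.K)

    kfold_results: dict[str, dict[str, CVResult]] = {}
    residual_vgs: dict[str, dict[str, object]] = {}
    for spec in config.model_specs:
        kfold_results[spec.name] = {}
        residual_vgs[spec.name] = {}
        for strategy, folds in (("random", random_folds),
                                ("spatial", spatial_folds)):
            if folds.K < 2:
                continue
            res = stage(f"kfold_{strategy}_{spec.name}", run_kfold_cv,
                        spec, sample_set, folds)
            kfold_results[spec.name][strategy] = res
            residual_vgs[spec.name][strategy] = residual_variogram(
                res.observed, res.predicted, sample_set.coords,
                config.variogram_bin_width_km, config.variogram_max_lag_km,
            )

    bloo_curves: dict[str, BlooCurve] = {}
    if config.run_bloo:
        rse_spec = next((s for s in config.model_specs if s.name == "RF_RSE"),
                        None)
        domain_cols = (rse_spec.predictor_columns(sample_set)
                       if rse_spec is not None else None)
        for spec in config.model_specs:
            bloo_curves[spec.name] = stage(
                f"bloo_{spec.name}", bloo_cv, spec, sample_set,
                config.bloo_radii_km, config.bloo_n_test, config.bloo_n_reps,
                stage_seed(config.master_seed, "bloo"),
                True, domain_cols,
            )

    report = None
    if bloo_curves:
        spatial_r2 = {
            name: res["spatial"].metrics.r2
            for name, res in kfold_results.items() if "spatial" in res
        }
        null_curve = bloo_curves.get("NULL")
        report = skill_vs_distance_report(
            bloo_curves, spatial_kfold_r2=spatial_r2, null_curve=null_curve,
        )

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {s: stage_seed(config.master_seed, s)
                        for s in STAGE_SEED_OFFSETS},
        "n_samples": len(sample_set),
        "spatial_K": spatial_folds.K,
        "model_specs": [s.to_dict() for s in config.model_specs],
        "scenario": (config.scenario.to_dict()
                     if config.scenario is not None else None),
        "input_csv": config.input_csv,
        "wall_time_s": None,
        "library_versions": _library_versions(),
    }

    if out is not None:
        sample_set.to_csv(out / "sample_set.csv")
        sample_set.write_sidecar(out / "sample_set.provenance.json")
        if filter_report is not None:
            filter_report.to_json(out / "filter_report.json")
        response_vg.to_csv(out / "variogram_response.csv")
        for name, by_strategy in kfold_results.items():
            for strategy, res in by_strategy.items():
                _write_csv(res.to_frame(), out / f"cv_{strategy}_{name}.csv")
                residual_vgs[name][strategy].to_csv(
                    out / f"residual_variogram_{strategy}_{name}.csv")
        for name, curve in bloo_curves.items():
            _write_csv(curve.to_frame(), out / f"bloo_{name}.csv")
        if report is not None:
            _write_csv(report, out / "skill_report.csv")

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)

    return ExperimentResult(
        sample_set=sample_set,
        filter_report=filter_report,
        response_variogram=response_vg,
        kfold_results=kfold_results,
        bloo_curves=bloo_curves,
        report=report,
        manifest=manifest,
    )


def skill_vs_distance_report(bloo_curves: dict[str, BlooCurve],
                             spatial_kfold_r2: dict[str, float] | None = None,
                             null_curve: BlooCurve | None = None) -> pd.DataFrame:
    """One table: R² and RMSPE (mean ± SD) per radius and model.

    The null model's RMSPE column is the no-skill reference line, and each
    model's spatial K-fold R² is repeated as a horizontal reference — the
    two benchmarks against which the decaying B-LOO curves are read.
    """
    curves = list(bloo_curves.values())
    if not curves:
        raise ValueError("no B-LOO curves supplied")
    radii = curves[0].radii_km
    for c in curves[1:]:
        if not np.array_equal(c.radii_km, radii):
            raise ValueError("B-LOO curves use different radius schedules")
    table = pd.DataFrame({"radius_km": radii})
    for name, curve in bloo_curves.items():
        table[f"{name}_r2_mean"] = curve.r2_mean
        table[f"{name}_r2_sd"] = curve.r2_sd
        table[f"{name}_rmspe_mean"] = curve.rmspe_mean
        table[f"{name}_rmspe_sd"] = curve.rmspe_sd
    if null_curve is not None and "NULL" not in bloo_curves:
        table["NULL_rmspe_mean"] = null_curve.rmspe_mean
    if spatial_kfold_r2:
        for name, r2 in spatial_kfold_r2.items():
            table[f"{name}_spatial_kfold_r2"] = r2
    return table


def geolocation_diagnostic(sample_set: SampleSet, n_train: int = 500,
                           master_seed: int = 0, n_trees: int = 500):
    """Reverse diagnostic: how well do covariates encode location?"""
    return predict_coordinates(sample_set, n_train=n_train,
                               seed=stage_seed(master_seed, "geopredict"),
                               n_trees=n_trees)


def _library_versions() -> dict:
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
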