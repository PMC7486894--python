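"""Canned desk-scale audit experiments with reportable summaries.

These functions wrap :func:`spatialcv.pipeline.run_experiment` into the
package's two headline experiments:

* the **spurious-skill audit** — a zero-effect landscape (predictors carry
  no information about the response) with clustered sampling, where random
  K-fold CV nevertheless reports substantial skill while buffered
  leave-one-out CV beyond the response's autocorrelation range reveals
  none; and
* the **genuine-signal control** — covariates truly drive the response,
  and spatially blocked CV must still report the real skill.

Problem sizes are desk-scale: n = 2000 samples, a 100-tree half-subsampled
audit forest, 50 B-LOO test points × 3 repetitions over radii 0–150 km by
30.  They keep a full multi-seed audit in the minutes range while leaving
every qualitative contrast far from its decision boundary.
"""

from __future__ import annotations

import numpy as np

from .crossval import run_kfold_cv
from .folds import random_kfold_split, spatial_kfold_split
from .models import ModelSpec, predict_coordinates
from .pipeline import ExperimentConfig, run_experiment
from .synthetic import (
    FieldSpec,
    ScenarioConfig,
    build_scenario,
    genuine_signal_scenario,
    spurious_skill_scenario,
)
from .variogram import empirical_variogram, estimate_range

#: Reduced B-LOO radius schedule for desk-scale audits (km).
AUDIT_RADII = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)

#: Audit-forest hyperparameters (see module docstring).
AUDIT_FOREST = dict(n_trees=100, max_samples=0.5, min_samples_leaf=5)


def audit_model_specs(seed: int) -> tuple[ModelSpec, ...]:
    return (
        ModelSpec("RF_RSE", seed=seed, **AUDIT_FOREST),
        ModelSpec("RF_XY", seed=seed, **AUDIT_FOREST),
        ModelSpec("NULL", seed=seed),
    )


def spurious_skill_audit(master_seed: int, n_test: int = 50, n_reps: int = 3,
                         radii_km: tuple[float, ...] = AUDIT_RADII) -> dict:
    """Run the full zero-effect audit for one master seed.

    Returns a flat summary: random and spatial K-fold R²/RMSPE per model,
    and the B-LOO R²/RMSPE curves (means over repetitions) per model.
    """
    config = ExperimentConfig(
        scenario=spurious_skill_scenario(seed=master_seed),
        model_specs=audit_model_specs(master_seed),
        bloo_radii_km=radii_km,
        bloo_n_test=n_test,
        bloo_n_reps=n_reps,
        master_seed=master_seed,
    )
    result = run_experiment(config)
    summary = {"radii_km": np.asarray(radii_km), "spatial_K":
               result.manifest["spatial_K"]}
    for name, by_strategy in result.kfold_results.items():
        for strategy, res in by_strategy.items():
            summary[f"{strategy}_cv_r2_{name}"] = res.metrics.r2
            summary[f"{strategy}_cv_rmspe_{name}"] = res.metrics.rmspe
    for name, curve in result.bloo_curves.items():
        summary[f"bloo_r2_{name}"] = curve.r2_mean
        summary[f"bloo_rmspe_{name}"] = curve.rmspe_mean
    return summary


def aggregate_audits(summaries: list[dict]) -> dict:
    """Average scalar and per-radius entries over master seeds."""
    out = {"n_seeds": len(summaries), "radii_km": summaries[0]["radii_km"]}
    for key in summaries[0]:
        if key in ("radii_km", "spatial_K"):
            continue
        out[key] = np.mean([s[key] for s in summaries], axis=0)
    return out


def genuine_signal_audit(master_seed: int) -> dict:
    """Spatially blocked CV on a landscape with a real covariate effect."""
    sample_set = build_scenario(genuine_signal_scenario(seed=master_seed))
    folds = spatial_kfold_split(sample_set.coords)
    spec = ModelSpec("RF_RSE", seed=master_seed, **AUDIT_FOREST)
    res = run_kfold_cv(spec, sample_set, folds)
    random_folds = random_kfold_split(len(sample_set), 10, master_seed)
    res_random = run_kfold_cv(spec, sample_set, random_folds)
    return {
        "spatial_K": folds.K,
        "spatial_cv_r2": res.metrics.r2,
        "spatial_cv_rmspe": res.metrics.rmspe,
        "random_cv_r2": res_random.metrics.r2,
    }


def range_recovery(true_range_km: float, n_seeds: int = 10,
                   n_samples: int = 1000, seed0: int = 100) -> dict:
    """Practical-range recovery from simulated fields, averaged over seeds."""
    estimates = []
    for s in range(n_seeds):
        config = ScenarioConfig(
            extent=(1000.0, 1000.0), n_samples=n_samples, layout="uniform",
            field_specs=(), effect_coefficients=(),
            response_spatial=FieldSpec("rs", "exponential", true_range_km, 1.0),
            iid_noise_sd=0.0, seed=seed0 + s,
        )
        ss = build_scenario(config)
        vg = empirical_variogram(ss.response, ss.coords, bin_width=20.0,
                                 max_lag=500.0)
        est = estimate_range(vg, "exponential")
        if est.spatial_structure:
            estimates.append(est.range_km)
    return {
        "true_range_km": true_range_km,
        "mean_estimate_km": float(np.mean(estimates)),
        "n_converged": len(estimates),
        "relative_error": float(abs(np.mean(estimates) - true_range_km)
                                / true_range_km),
    }


def geolocation_audit(master_seed: int, n_predictors: int = 25,
                      n_train: int = 500) -> dict:
    """Reverse location-prediction diagnostic on a clustered landscape."""
    ss = build_scenario(spurious_skill_scenario(seed=master_seed,
                                                n_predictors=n_predictors))
    res = predict_coordinates(ss, n_train=n_train, seed=master_seed,
                              n_trees=200)
    return {
        "rmse_km": res.rmse_km,
        "baseline_rmse_km": res.baseline_rmse_km,
        "n_train": res.n_train,
        "n_test": res.n_test,
    }
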