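"""Cross-validation strategies for spatially autocorrelated data.

Three strategies are implemented.  Random K-fold CV ignores location and
is the optimistic baseline under audit.  Spatial K-fold CV evaluates on
geographically compact held-out clusters.  Buffered leave-one-out CV
(B-LOO) evaluates one test sample at a time while excluding *all* training
samples within a buffer radius r of it; sweeping r from zero past the
autocorrelation range of the response traces exactly how much of the
model's apparent skill is spatial proximity rather than covariate
information.

B-LOO includes an extrapolation safeguard: candidate test samples whose
covariate values fall outside the training range after maximal buffering
are rejected, so that the skill decay measured is attributable to lost
spatial dependence, not to forcing the model outside its calibration
domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .folds import SpatialFolds
from .metrics import MetricSet, metric_set
from .models import ModelSpec, fit_predict
from .synthetic import SampleSet
from .variogram import pairwise_distances

#: Buffer radii of the default B-LOO sweep: 0..150 km by 10 km.
DEFAULT_BLOO_RADII = tuple(float(r) for r in range(0, 151, 10))

#: Candidate-draw budget of the extrapolation safeguard, per n_test.
SAFEGUARD_BUDGET_FACTOR = 50


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold predictions and their CV statistics."""

    observed: np.ndarray
    predicted: np.ndarray
    fold_id: np.ndarray
    model_name: str
    folds_method: str
    K: int
    metrics: MetricSet

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed": self.observed,
            "predicted": self.predicted,
            "fold_id": self.fold_id,
        })


@dataclass(frozen=True)
class BlooCurve:
    """Per-radius B-LOO statistics (mean ± SD over repetitions).

    ``r2`` entries may be NaN for a repetition where predictions were
    constant (Pearson correlation undefined); means/SDs then ignore those
    repetitions.  ``n_discarded_by_safeguard`` counts candidate test
    samples rejected by the extrapolation check.
    """

    model_name: str
    radii_km: np.ndarray
    r2_by_rep: np.ndarray      # (n_reps, n_radii)
    rmspe_by_rep: np.ndarray   # (n_reps, n_radii)
    n_test: int
    n_reps: int
    n_discarded_by_safeguard: int = 0
    training_counts: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if np.any(np.diff(self.radii_km) <= 0):
            raise ValueError("radii must be strictly increasing")

    @property
    def r2_mean(self) -> np.ndarray:
        return np.nanmean(self.r2_by_rep, axis=0)

    @property
    def r2_sd(self) -> np.ndarray:
        return np.nanstd(self.r2_by_rep, axis=0)

    @property
    def rmspe_mean(self) -> np.ndarray:
        return self.rmspe_by_rep.mean(axis=0)

    @property
    def rmspe_sd(self) -> np.ndarray:
        return self.rmspe_by_rep.std(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "radius_km": self.radii_km,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "rmspe_mean": self.rmspe_mean,
            "rmspe_sd": self.rmspe_sd,
            "model": self.model_name,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_kfold_cv(spec: ModelSpec, sample_set: SampleSet,
                 folds: SpatialFolds) -> CVResult:
    """K-fold CV: each sample predicted once by a model blind to its fold.

    Metrics are computed on the pooled out-of-fold prediction vector, as
    in standard mapping-model validation.
    """
    n = len(sample_set)
    if len(folds.fold_id) != n:
        raise ValueError("folds do not cover the sample set")
    if folds.K < 2:
        raise ValueError("K-fold CV needs at least 2 folds")
    predicted = np.full(n, np.nan)
    for train_idx, test_idx in folds.split():
        if len(test_idx) == n:
            raise ValueError("a fold equals the whole sample set")
        predicted[test_idx] = fit_predict(
            spec, sample_set.subset(train_idx), sample_set.subset(test_idx)
        )
    observed = sample_set.response
    return CVResult(
        observed=observed,
        predicted=predicted,
        fold_id=folds.fold_id.copy(),
        model_name=spec.name,
        folds_method=folds.method,
        K=folds.K,
        metrics=metric_set(observed, predicted),
    )


def domain_check(test_row: pd.Series, training: pd.DataFrame,
                 covariate_columns: list[str]) -> bool:
    """True iff the test sample lies inside the training calibration domain.

    Continuous covariates must fall within the training [min, max];
    categorical covariates must take a level present in training.  An
    empty training set has no domain, hence False.
    """
    if len(training) == 0:
        return False
    for col in covariate_columns:
        train_col = training[col]
        value = test_row[col]
        if pd.api.types.is_numeric_dtype(train_col):
            if not (train_col.min() <= value <= train_col.max()):
                return False
        else:
            if value not in set(train_col):
                return False
    return True


def _select_test_samples(sample_set: SampleSet, distances: np.ndarray,
                         r_max: float, n_test: int,
                         rng: np.random.Generator,
                         covariate_columns: list[str],
                         safeguard: bool) -> tuple[np.ndarray, int]:
    """Draw test samples, applying the extrapolation safeguard at r_max.

    Candidates are drawn without replacement; those failing the domain
    check after maximal buffering are discarded and redrawn, within a
    budget of ``SAFEGUARD_BUDGET_FACTOR * n_test`` draws.  On exhaustion
    the (smaller) accepted set is returned.
    """
    n = len(sample_set)
    order = rng.permutation(n)
    if not safeguard:
        return order[:n_test], 0
    frame = sample_set.frame
    accepted: list[int] = []
    discarded = 0
    budget = SAFEGUARD_BUDGET_FACTOR * n_test
    for idx in order[:budget]:
        train_mask = distances[idx] > r_max
        training = frame.loc[train_mask]
        if domain_check(frame.iloc[idx], training, covariate_columns):
            accepted.append(idx)
            if len(accepted) == n_test:
                break
        else:
            discarded += 1
    return np.asarray(accepted, dtype=int), discarded


def bloo_cv(spec: ModelSpec, sample_set: SampleSet,
            radii_km=DEFAULT_BLOO_RADII, n_test: int = 100,
            n_reps: int = 10, seed: int = 0,
            safeguard: bool = True,
            domain_columns: list[str] | None = None) -> BlooCurve:
    """Buffered leave-one-out CV over a sweep of exclusion radii.

    Per repetition, ``n_test`` test samples are drawn (without replacement
    within a repetition; repetition seeds are ``seed + rep``).  For each
    radius r, the model trains on all samples strictly farther than r from
    the test sample — the test sample itself and its closed r-ball are
    excluded — and predicts it.  R² and RMSPE are computed per
    (repetition, radius) over the pooled n_test predictions, then
    summarized as mean ± SD over repetitions.

    ``domain_columns`` fixes the covariate set used by the extrapolation
    safeguard.  Passing the covariate-model's predictor list when auditing
    several models under the same seed makes every model see identical
    test draws, so their curves are directly comparable.
    """
    radii = np.asarray(radii_km, dtype=float)
    if radii.ndim != 1 or len(radii) == 0 or np.any(radii < 0):
        raise ValueError("radii must be non-negative")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    n = len(sample_set)
    if not 0 < n_test < n:
        raise ValueError("n_test must satisfy 0 < n_test < n")

    distances = pairwise_distances(sample_set.coords)
    if domain_columns is not None:
        check_columns = list(domain_columns)
    elif spec.name == "RF_RSE":
        check_columns = spec.predictor_columns(sample_set)
    else:
        # coordinate and null models have no covariate domain to leave
        check_columns = []

    r2 = np.full((n_reps, len(radii)), np.nan)
    rmspe_arr = np.zeros((n_reps, len(radii)))
    train_counts = np.zeros((n_reps, len(radii)))
    total_discarded = 0
    observed_all = sample_set.response
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        test_idx, discarded = _select_test_samples(
            sample_set, distances, float(radii[-1]), n_test, rng,
            check_columns, safeguard=safeguard and bool(check_columns),
        )
        total_discarded += discarded
        if len(test_idx) == 0:
            raise RuntimeError("extrapolation safeguard rejected every candidate")
        observed = observed_all[test_idx]
        for j, r in enumerate(radii):
            preds = np.empty(len(test_idx))
            counts = 0
            for t, idx in enumerate(test_idx):
                train_mask = distances[idx] > r
                if not train_mask.any():
                    raise ValueError(
                        f"training set empty at radius {r} km for sample {idx}"
                    )
                counts += int(train_mask.sum())
                preds[t] = fit_predict(
                    spec,
                    sample_set.subset(np.flatnonzero(train_mask)),
                    sample_set.subset([idx]),
                )[0]
            m = metric_set(observed, preds)
            r2[rep, j] = m.r2
            rmspe_arr[rep, j] = m.rmspe
            train_counts[rep, j] = counts / len(test_idx)
    return BlooCurve(
        model_name=spec.name,
        radii_km=radii,
        r2_by_rep=r2,
        rmspe_by_rep=rmspe_arr,
        n_test=n_test,
        n_reps=n_reps,
        n_discarded_by_safeguard=total_discarded,
        training_counts=train_counts,
    )
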