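"""The competing predictors: covariate forest, coordinate forest, null model.

Three model specs frame the audit.  ``RF_RSE`` is a random-forest
regression on remote-sensing/environmental covariates — the mapping model
under scrutiny.  ``RF_XY`` uses only the two geographic coordinates: a
model with no environmental information whatsoever, whose skill is pure
spatial interpolation.  ``NULL`` predicts the training mean regardless of
inputs.  If RF_RSE cannot beat RF_XY, its covariates carry no information
beyond encoding location; if it cannot beat NULL at spatial distance, it
has no transferable skill at all.

Also provides the reverse diagnostic: predicting sample *coordinates*
from the covariates.  A low coordinate RMSE demonstrates that covariate
combinations are location fingerprints, which is the mechanism by which
spatial leakage masquerades as predictive skill.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor

from .synthetic import SampleSet

MODEL_NAMES = ("RF_RSE", "RF_XY", "NULL")
COORD_COLUMNS = ("x_km", "y_km")


@dataclass(frozen=True)
class ModelSpec:
    """Serializable description of one predictor.

    ``predictors`` lists covariate columns for RF_RSE (None = all
    covariates of the sample set); RF_XY always uses exactly the two
    coordinate columns and NULL ignores predictors entirely.  Forest
    hyperparameters follow regression conventions: variables-per-split
    ⌈p/3⌉, small leaves; ``max_samples`` optionally subsamples each
    bootstrap for cheaper ensembles.
    """

    name: str
    predictors: tuple[str, ...] | None = None
    n_trees: int = 500
    min_samples_leaf: int = 5
    max_samples: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}")

    def predictor_columns(self, sample_set: SampleSet) -> list[str]:
        if self.name == "NULL":
            return []
        if self.name == "RF_XY":
            return list(COORD_COLUMNS)
        if self.predictors is not None:
            return list(self.predictors)
        return sample_set.covariate_names

    def to_dict(self) -> dict:
        return asdict(self)


def make_estimator(spec: ModelSpec, n_features: int):
    """Instantiate the sklearn estimator behind a model spec."""
    if spec.name == "NULL":
        return DummyRegressor(strategy="mean")
    return RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=max(1, math.ceil(n_features / 3)),
        min_samples_leaf=spec.min_samples_leaf,
        max_samples=spec.max_samples,
        random_state=spec.seed,
        n_jobs=1,
    )


def design_matrix(spec: ModelSpec, sample_set: SampleSet,
                  columns: list[str] | None = None) -> np.ndarray:
    cols = columns if columns is not None else spec.predictor_columns(sample_set)
    if not cols:
        return np.zeros((len(sample_set), 1))
    missing = [c for c in cols if c not in sample_set.frame.columns]
    if missing:
        raise ValueError(f"predictor columns missing from sample set: {missing}")
    return sample_set.frame[cols].to_numpy(dtype=float)


def fit_predict(spec: ModelSpec, train: SampleSet, test: SampleSet) -> np.ndarray:
    """Train the spec's estimator on ``train`` and predict ``test``.

    Deterministic under a fixed spec seed and fixed data.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    cols = spec.predictor_columns(train)
    est = make_estimator(spec, max(1, len(cols)))
    est.fit(design_matrix(spec, train, cols), train.response)
    return est.predict(design_matrix(spec, test, cols))


@dataclass(frozen=True)
class CoordinatePrediction:
    """Result of the reverse location-prediction diagnostic.

    ``rmse_km`` is the root mean squared Euclidean distance between true
    and predicted coordinates on held-out samples.  ``baseline_rmse_km``
    is the no-skill reference: the RMS distance of held-out points from
    the training centroid (the best constant prediction).
    """

    rmse_km: float
    rmse_x_km: float
    rmse_y_km: float
    baseline_rmse_km: float
    n_train: int
    n_test: int


def predict_coordinates(sample_set: SampleSet, n_train: int = 500,
                        seed: int = 0, covariates: list[str] | None = None,
                        n_trees: int = 500) -> CoordinatePrediction:
    """Predict sample coordinates from covariates with a multi-output forest.

    Trains one multi-output random-forest regression (both coordinates as
    joint targets, averaged-variance split criterion) on ``n_train``
    randomly drawn samples and evaluates on the rest.
    """
    n = len(sample_set)
    if not 0 < n_train < n:
        raise ValueError("n_train must satisfy 0 < n_train < n")
    cols = covariates if covariates is not None else sample_set.covariate_names
    if not cols:
        raise ValueError("no covariate columns available")
    rng = np.random.default_rng(seed)
    train_idx = rng.choice(n, size=n_train, replace=False)
    test_idx = np.setdiff1d(np.arange(n), train_idx)

    X = sample_set.frame[cols].to_numpy(dtype=float)
    Y = sample_set.coords
    est = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, math.ceil(len(cols) / 3)),
        min_samples_leaf=5,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X[train_idx], Y[train_idx])
    pred = est.predict(X[test_idx])
    err = Y[test_idx] - pred
    sq_dist = np.sum(err**2, axis=1)
    centroid = Y[train_idx].mean(axis=0)
    base_sq = np.sum((Y[test_idx] - centroid) ** 2, axis=1)
    return CoordinatePrediction(
        rmse_km=float(np.sqrt(sq_dist.mean())),
        rmse_x_km=float(np.sqrt((err[:, 0] ** 2).mean())),
        rmse_y_km=float(np.sqrt((err[:, 1] ** 2).mean())),
        baseline_rmse_km=float(np.sqrt(base_sq.mean())),
        n_train=n_train,
        n_test=len(test_idx),
    )
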