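"""Synthetic geostatistical scenarios with controllable spatial structure.

Large-scale ecological mapping studies train models on point samples whose
response and covariates are both spatially autocorrelated, and whose
sampling layout is strongly clustered (dense patches inside surveyed
areas, huge unsampled swaths elsewhere).  This module generates such data
from first principles — stationary Gaussian random fields on planar km
coordinates, clustered or uniform sampling layouts, and a linear
predictor→response effect structure with tunable coefficients (including
zero effect, the regime where any apparent cross-validation skill is pure
spatial leakage).  Every scenario is fully reproducible from its config.

Coordinates are planar km in an abstract projection; at the few-hundred-km
scale of interest, geodesy is irrelevant to the statistical point being
made.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

#: Dense-factorization cap for one field simulation.  The simulator builds
#: and Cholesky-factorizes the full n x n covariance, exact but O(n^3).
MAX_GRF_N = 6000

#: Default nugget fraction (of the sill) for AGB-like response fields where
#: no empirical small-scale variance is available.
DEFAULT_NUGGET_FRACTION = 0.3

_COVARIANCE_MODELS = ("exponential", "spherical", "nugget")


@dataclass(frozen=True)
class FieldSpec:
    """One stationary Gaussian random field: name, covariance model and moments."""

    name: str
    model: str = "exponential"
    range_km: float = 300.0
    sill: float = 1.0
    nugget: float = 0.0
    mean: float = 0.0

    def __post_init__(self):
        if self.model not in _COVARIANCE_MODELS:
            raise ValueError(f"unknown covariance model {self.model!r}")
        if self.model != "nugget" and self.range_km <= 0:
            raise ValueError("range must be positive for non-nugget models")
        if self.sill < 0 or self.nugget < 0:
            raise ValueError("sill and nugget must be non-negative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic landscape + sampling + effects.

    ``effect_coefficients`` are the true linear coefficients β linking each
    covariate field to the response; ``response_spatial`` is the residual
    spatial field added on top, and ``iid_noise_sd`` the unstructured
    measurement noise.  Identical configs (same seed) regenerate identical
    sample sets.
    """

    extent: tuple[float, float] = (1000.0, 1000.0)
    n_samples: int = 2000
    layout: str = "clustered"
    n_clusters: int = 40
    cluster_radius_km: float = 20.0
    field_specs: tuple[FieldSpec, ...] = ()
    effect_coefficients: tuple[float, ...] = ()
    response_spatial: FieldSpec = field(
        default_factory=lambda: FieldSpec("response_spatial", "exponential",
                                          120.0, 1.0)
    )
    iid_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.layout not in ("uniform", "clustered"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.layout == "clustered":
            if self.n_clusters < 1:
                raise ValueError("n_clusters must be >= 1")
            if self.cluster_radius_km < 0:
                raise ValueError("cluster_radius_km must be >= 0")
            if self.n_samples % self.n_clusters:
                raise ValueError(
                    "n_samples must be divisible by n_clusters (fixed cluster "
                    "membership counts keep scenarios deterministic)"
                )
        if self.effect_coefficients and len(self.effect_coefficients) != len(
            self.field_specs
        ):
            raise ValueError("one effect coefficient per covariate field required")
        if self.iid_noise_sd < 0:
            raise ValueError("iid_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["extent"] = tuple(d["extent"])
        d["field_specs"] = tuple(FieldSpec(**fs) for fs in d.get("field_specs", ()))
        d["effect_coefficients"] = tuple(d.get("effect_coefficients", ()))
        rs = d.get("response_spatial")
        if isinstance(rs, dict):
            d["response_spatial"] = FieldSpec(**rs)
        return cls(**d)


class SampleSet:
    """Point-sample table: coordinates, response, covariates, QC attributes.

    Thin, validated wrapper over a pandas DataFrame with reserved columns
    ``id``, ``x_km``, ``y_km``, ``response``; all remaining columns are
    covariates unless named in ``qc_columns``.
    """

    RESERVED = ("id", "x_km", "y_km", "response")

    def __init__(self, frame: pd.DataFrame, qc_columns: tuple[str, ...] = (),
                 provenance: dict | None = None,
                 allow_duplicate_coordinates: bool = False):
        missing = [c for c in self.RESERVED if c not in frame.columns]
        if missing:
            raise ValueError(f"SampleSet missing required columns: {missing}")
        if frame["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        xy = frame[["x_km", "y_km"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("coordinates must be finite")
        if frame.columns.duplicated().any():
            raise ValueError("column names must be unique")
        if not allow_duplicate_coordinates and len(frame) > 1:
            if frame.duplicated(subset=["x_km", "y_km"]).any():
                raise ValueError(
                    "duplicated coordinate pairs (pass "
                    "allow_duplicate_coordinates=True to permit)"
                )
        unknown_qc = set(qc_columns) - set(frame.columns)
        if unknown_qc:
            raise ValueError(f"qc columns not in table: {sorted(unknown_qc)}")
        self.frame = frame.reset_index(drop=True)
        self.qc_columns = tuple(qc_columns)
        self.provenance = dict(provenance or {})
        self._allow_dup = allow_duplicate_coordinates

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x_km", "y_km"]].to_numpy(dtype=float)

    @property
    def response(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=float)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns
                if c not in self.RESERVED and c not in self.qc_columns]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame[self.covariate_names]

    def subset(self, indices) -> "SampleSet":
        return SampleSet(self.frame.iloc[np.asarray(indices)].copy(),
                         qc_columns=self.qc_columns,
                         provenance=self.provenance,
                         allow_duplicate_coordinates=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def write_sidecar(self, path) -> None:
        """Scenario provenance (true β, true ranges, seed) as JSON."""
        with open(path, "w") as fh:
            json.dump({"qc_columns": list(self.qc_columns),
                       "provenance": self.provenance}, fh, indent=2,
                      default=_json_default)

    @classmethod
    def from_csv(cls, path, qc_columns: tuple[str, ...] = (),
                 allow_duplicate_coordinates: bool = True) -> "SampleSet":
        return cls(pd.read_csv(path), qc_columns=qc_columns,
                   allow_duplicate_coordinates=allow_duplicate_coordinates)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _covariance_matrix(d: np.ndarray, model: str, range_km: float, sill: float,
                       nugget: float) -> np.ndarray:
    if model == "nugget":
        c = np.zeros_like(d)
    elif model == "exponential":
        c = sill * np.exp(-3.0 * d / range_km)
    elif model == "spherical":
        hr = np.clip(d / range_km, 0.0, 1.0)
        c = sill * (1.0 - 1.5 * hr + 0.5 * hr**3)
    else:
        raise ValueError(f"unknown covariance model {model!r}")
    np.fill_diagonal(c, sill + nugget)
    return c


def simulate_grf(coords, model: str = "exponential", range_km: float = 120.0,
                 sill: float = 1.0, nugget: float = 0.0, mean: float = 0.0,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one realization of a stationary Gaussian random field.

    Uses exact dense covariance factorization (Cholesky with a small
    escalating diagonal jitter), capped at ``MAX_GRF_N`` points.  The
    exponential model is parameterized by its practical range, i.e.
    correlation exp(−3h/range).
    """
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or not np.isfinite(xy).all():
        raise ValueError("coords must be a finite (n, 2) array")
    n = len(xy)
    FieldSpec("_", model, range_km if model != "nugget" else 1.0,
              sill, nugget, mean)  # reuse parameter validation
    if rng is None:
        rng = np.random.default_rng(seed)

    if sill == 0.0 and nugget == 0.0:
        # degenerate process: still consume randomness for rng-threading
        rng.standard_normal(n)
        return np.full(n, float(mean))
    if model == "nugget" or sill == 0.0:
        return mean + np.sqrt(sill + nugget) * rng.standard_normal(n)
    if n > MAX_GRF_N:
        raise ValueError(f"n={n} exceeds dense-factorization cap {MAX_GRF_N}")

    d = squareform(pdist(xy)) if n > 1 else np.zeros((1, 1))
    cov = _covariance_matrix(d, model, range_km, sill, nugget)
    scale = sill + nugget
    for jitter in (1e-10, 1e-8, 1e-6):
        try:
            chol = np.linalg.cholesky(cov + jitter * scale * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError(
            "covariance factorization failed even with 1e-6 relative jitter"
        )
    return mean + chol @ rng.standard_normal(n)


def sample_uniform_layout(extent, n_samples: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniformly random coordinates over a rectangular extent (km)."""
    w, h = extent
    if w <= 0 or h <= 0:
        raise ValueError("extent must be positive")
    return np.column_stack([rng.uniform(0, w, n_samples),
                            rng.uniform(0, h, n_samples)])


def sample_clustered_layout(extent, n_clusters: int, points_per_cluster: int,
                            cluster_radius_km: float,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Clustered sampling: dense patches, large unsampled swaths.

    Cluster centers are uniform over the extent; members are isotropic
    Gaussian offsets with scale ``cluster_radius_km``, redrawn until inside
    the extent.  Membership counts are fixed (not Poisson) so layouts are
    deterministic in size.
    """
    w, h = extent
    if w <= 0 or h <= 0:
        raise ValueError("extent must be positive")
    if n_clusters < 1 or points_per_cluster < 1:
        raise ValueError("n_clusters and points_per_cluster must be >= 1")
    if cluster_radius_km < 0:
        raise ValueError("cluster_radius_km must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    centers = np.column_stack([rng.uniform(0, w, n_clusters),
                               rng.uniform(0, h, n_clusters)])
    pts = np.empty((n_clusters * points_per_cluster, 2))
    k = 0
    for cx, cy in centers:
        drawn = 0
        while drawn < points_per_cluster:
            off = rng.normal(0.0, cluster_radius_km, size=2) if cluster_radius_km else np.zeros(2)
            x, y = cx + off[0], cy + off[1]
            if 0.0 <= x <= w and 0.0 <= y <= h:
                pts[k] = (x, y)
                k += 1
                drawn += 1
    return pts


def build_scenario(config: ScenarioConfig) -> SampleSet:
    """Materialize a scenario: layout, covariate fields, response, noise.

    response = Σ βⱼ·covariateⱼ + residual spatial field + iid noise.
    Provenance (true β, true ranges, seed) rides along on the returned
    SampleSet for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    if config.layout == "uniform":
        coords = sample_uniform_layout(config.extent, config.n_samples, rng)
    else:
        coords = sample_clustered_layout(
            config.extent, config.n_clusters,
            config.n_samples // config.n_clusters,
            config.cluster_radius_km, rng=rng,
        )

    covariates = {}
    for fs in config.field_specs:
        covariates[fs.name] = simulate_grf(
            coords, fs.model, fs.range_km, fs.sill, fs.nugget, fs.mean, rng=rng
        )
    beta = np.asarray(config.effect_coefficients or
                      np.zeros(len(config.field_specs)), dtype=float)
    rs = config.response_spatial
    residual_field = simulate_grf(coords, rs.model, rs.range_km, rs.sill,
                                  rs.nugget, rs.mean, rng=rng)
    noise = (rng.normal(0.0, config.iid_noise_sd, config.n_samples)
             if config.iid_noise_sd > 0 else np.zeros(config.n_samples))

    effect = np.zeros(config.n_samples)
    for b, fs in zip(beta, config.field_specs):
        if b:
            effect += b * covariates[fs.name]
    response = effect + residual_field + noise

    frame = pd.DataFrame({
        "id": np.arange(config.n_samples),
        "x_km": coords[:, 0],
        "y_km": coords[:, 1],
        "response": response,
    })
    for name, vals in covariates.items():
        frame[name] = vals
    provenance = {
        "config": config.to_dict(),
        "true_beta": beta.tolist(),
        "true_ranges_km": {fs.name: fs.range_km for fs in config.field_specs},
        "response_range_km": rs.range_km,
        "seed": config.seed,
    }
    return SampleSet(frame, provenance=provenance,
                     allow_duplicate_coordinates=(config.layout == "clustered"
                                                  and config.cluster_radius_km == 0))


def spurious_skill_scenario(seed: int = 0, n_samples: int = 2000,
                            n_predictors: int = 5,
                            predictor_range_km: float = 300.0,
                            response_range_km: float = 120.0,
                            noise_variance_fraction: float = 0.10) -> ScenarioConfig:
    """Zero-effect scenario where all CV skill is spatial leakage.

    Predictors are long-range fields (β = 0 for all), the response is an
    independent shorter-range field plus iid noise whose variance is
    ``noise_variance_fraction`` of the spatial sill.  Any skill a random
    CV reports on this landscape is an artifact of spatial proximity
    between training and test samples.
    """
    fields = tuple(
        FieldSpec(f"cov{i + 1}", "exponential", predictor_range_km, 1.0)
        for i in range(n_predictors)
    )
    return ScenarioConfig(
        extent=(1000.0, 1000.0),
        n_samples=n_samples,
        layout="clustered",
        n_clusters=40,
        cluster_radius_km=20.0,
        field_specs=fields,
        effect_coefficients=tuple(0.0 for _ in fields),
        response_spatial=FieldSpec("response_spatial", "exponential",
                                   response_range_km, 1.0),
        iid_noise_sd=float(np.sqrt(noise_variance_fraction)),
        seed=seed,
    )


def genuine_signal_scenario(seed: int = 0, n_samples: int = 2000,
                            n_predictors: int = 5,
                            signal_variance_fraction: float = 0.8) -> ScenarioConfig:
    """Control scenario where covariates truly drive the response.

    β = 1 on every predictor, no residual spatial field; iid noise sized so
    the covariates explain ``signal_variance_fraction`` of response
    variance.  A sound validation scheme must report real skill here.
    """
    if not 0 < signal_variance_fraction < 1:
        raise ValueError("signal_variance_fraction must be in (0, 1)")
    fields = tuple(
        FieldSpec(f"cov{i + 1}", "exponential", 300.0, 1.0)
        for i in range(n_predictors)
    )
    signal_var = float(n_predictors)  # independent unit-sill fields
    noise_var = signal_var * (1.0 - signal_variance_fraction) / signal_variance_fraction
    return ScenarioConfig(
        extent=(1000.0, 1000.0),
        n_samples=n_samples,
        layout="clustered",
        n_clusters=40,
        cluster_radius_km=20.0,
        field_specs=fields,
        effect_coefficients=tuple(1.0 for _ in fields),
        response_spatial=FieldSpec("response_spatial", "exponential", 120.0, 0.0),
        iid_noise_sd=float(np.sqrt(noise_var)),
        seed=seed,
    )
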