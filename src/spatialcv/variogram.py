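"""Empirical semivariograms and autocorrelation-range estimation.

The semivariogram γ(h) — half the mean squared difference between values a
lag distance h apart — is the standard diagnostic for spatial
autocorrelation in geostatistics.  This module provides the classical
Matheron estimator on binned lags, weighted least-squares fits of
exponential and spherical variogram models, and the practical range (the
lag beyond which spatial correlation is negligible).  Applied to a mapped
response, to its covariates, or to cross-validation residuals, these
diagnostics reveal the correlation structure that invalidates random
train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.spatial.distance import pdist, squareform

VARIOGRAM_MODELS = ("exponential", "spherical", "nugget")


def pairwise_distances(coords) -> np.ndarray:
    """Symmetric Euclidean distance matrix for planar coordinates in km."""
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of planar km coordinates")
    if not np.isfinite(xy).all():
        raise ValueError("coordinates must be finite")
    if len(xy) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(xy))


def theoretical_semivariance(h, model: str, range_km: float, sill: float,
                             nugget: float = 0.0) -> np.ndarray:
    """Model semivariance γ(h).

    The exponential model uses the practical-range parameterization
    γ(h) = nugget + sill·(1 − exp(−3h/range)), so ``range_km`` is the lag
    where the curve reaches ~95% of the sill, matching how "range of
    autocorrelation" is read off empirical variograms.  The spherical
    model uses the standard closed form and reaches the sill exactly at
    ``range_km``.
    """
    h = np.asarray(h, dtype=float)
    if model == "nugget":
        gamma = np.full_like(h, float(sill + nugget))
        return np.where(h == 0, 0.0, gamma)
    if range_km <= 0:
        raise ValueError(f"range must be positive for model {model!r}")
    if model == "exponential":
        struct = sill * (1.0 - np.exp(-3.0 * h / range_km))
    elif model == "spherical":
        hr = np.clip(h / range_km, 0.0, 1.0)
        struct = sill * (1.5 * hr - 0.5 * hr**3)
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return np.where(h == 0, 0.0, nugget + struct)


@dataclass(frozen=True)
class VariogramEstimate:
    """Binned empirical semivariogram.

    Bins with no pairs carry NaN semivariance (never 0.0) so that absent
    evidence is distinguishable from evidence of no variance.
    """

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    n_samples: int

    def __post_init__(self):
        if np.any(self.pair_counts < 0):
            raise ValueError("pair counts must be non-negative")
        populated = self.pair_counts > 0
        if np.any(self.semivariance[populated] < 0):
            raise ValueError("semivariance must be non-negative")
        total_pairs = self.n_samples * (self.n_samples - 1) // 2
        if self.pair_counts.sum() > total_pairs:
            raise ValueError("more pairs than n(n-1)/2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_km": self.bin_centers,
                "semivariance": self.semivariance,
                "pair_count": self.pair_counts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RangeEstimate:
    """Fitted variogram model and its practical range.

    ``spatial_structure`` is False when the fitted partial sill is
    negligible (flat variogram); ``range_km`` is NaN in that case rather
    than a spurious number.
    """

    model: str
    range_km: float
    sill: float
    nugget: float
    fit_sse: float
    spatial_structure: bool = True
    fitted_range_param: float = field(default=float("nan"))


def empirical_variogram(values, coords, bin_width: float = 10.0,
                        max_lag: float | None = None) -> VariogramEstimate:
    """Matheron semivariogram estimator on half-open distance bins.

    γ(h) = Σ_{pairs in bin} (z_i − z_j)² / (2 N(h)), with pairs assigned to
    bins [edge, edge + bin_width).  ``max_lag`` defaults to half the
    maximum pairwise distance, the conventional cutoff beyond which pair
    geometry makes the estimator unreliable.
    """
    z = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if z.ndim != 1 or len(z) != len(xy):
        raise ValueError("values must be 1-D and aligned with coords")
    if not np.isfinite(z).all():
        raise ValueError("values must be finite")
    if len(z) < 2:
        raise ValueError("need at least 2 samples for a variogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    d = pdist(xy)
    if not np.isfinite(d).all():
        raise ValueError("coordinates must be finite")
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")

    n_bins = int(np.ceil(max_lag / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    sq_diff = pdist(z[:, None], metric="sqeuclidean")
    keep = d < edges[-1]
    idx = np.floor(d[keep] / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq_diff[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    return VariogramEstimate(
        bin_edges=edges,
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        semivariance=gamma,
        pair_counts=counts,
        n_samples=len(z),
    )


def _practical_range(model: str, range_param: float, sill: float,
                     nugget: float) -> float:
    """Lag where the fitted curve reaches 95% of the total sill."""
    total = sill + nugget
    target = 0.95 * total
    if model == "exponential":
        # nugget + sill(1 - e^{-3h/a}) = 0.95(nugget + sill)
        arg = 0.05 * total / sill
        if arg >= 1.0:  # nugget alone already exceeds 95% of the sill
            return 0.0
        return float(-range_param / 3.0 * np.log(arg))
    # spherical: solve on (0, a]; γ(a) = sill + nugget >= target always
    f = lambda h: theoretical_semivariance(h, model, range_param, sill, nugget) - target
    if f(range_param) <= 0:
        return float(range_param)
    return float(brentq(f, 1e-9 * range_param, range_param))


def estimate_range(variogram: VariogramEstimate, model: str = "exponential",
                   rel_sill_tol: float = 1e-3) -> RangeEstimate:
    """Weighted least-squares fit of a variogram model; reports practical range.

    Weights are the per-bin pair counts.  Parameters are bounded below by
    zero (no negative nuggets).  A fitted partial sill below
    ``rel_sill_tol`` of the total sill flags absence of spatial structure
    instead of reporting a meaningless range.
    """
    if model not in ("exponential", "spherical"):
        raise ValueError(f"unsupported model for range estimation: {model!r}")
    ok = variogram.pair_counts > 0
    h = variogram.bin_centers[ok]
    g = variogram.semivariance[ok]
    w = variogram.pair_counts[ok].astype(float)
    if len(h) < 4:
        raise ValueError("need at least 4 populated bins to fit a variogram model")

    g_mean = float(g.mean())
    h_max = float(h.max())
    if g_mean <= 0:
        return RangeEstimate(model, float("nan"), 0.0, 0.0, 0.0,
                             spatial_structure=False)

    def residuals(params):
        a, sill, nugget = params
        return np.sqrt(w) * (theoretical_semivariance(h, model, a, sill, nugget) - g)

    # moment-based starting point: sill near the mean γ, range near h_max/2
    x0 = np.array([max(h_max / 2.0, 1e-6), g_mean, 0.0])
    fit = least_squares(
        residuals, x0,
        bounds=([1e-9, 0.0, 0.0], [10.0 * h_max, np.inf, np.inf]),
    )
    a, sill, nugget = fit.x
    sse = float(np.sum(fit.fun**2))
    total = sill + nugget
    if total <= 0 or sill < rel_sill_tol * total:
        return RangeEstimate(model, float("nan"), float(sill), float(nugget),
                             sse, spatial_structure=False,
                             fitted_range_param=float(a))
    return RangeEstimate(
        model=model,
        range_km=_practical_range(model, a, sill, nugget),
        sill=float(sill),
        nugget=float(nugget),
        fit_sse=sse,
        spatial_structure=True,
        fitted_range_param=float(a),
    )


def residual_variogram(observed, predicted, coords, bin_width: float = 10.0,
                       max_lag: float | None = None) -> VariogramEstimate:
    """Semivariogram of out-of-fold CV residuals (observed − predicted).

    Residual structure that survives cross-validation indicates a model
    missing the spatial component of the response; its *absence* after a
    random split does not certify the model, which is the central
    diagnostic trap this package audits.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be aligned")
    if np.isnan(pred).any():
        raise ValueError("missing out-of-fold predictions")
    return empirical_variogram(obs - pred, coords, bin_width=bin_width,
                               max_lag=max_lag)
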