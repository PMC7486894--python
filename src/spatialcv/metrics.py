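"""Validation statistics for spatial prediction models.

The conventions follow common usage in large-scale ecological mapping:
``R²`` is the squared Pearson correlation between observations and
out-of-sample predictions (not the coefficient of determination, which can
be negative), RMSPE is the root mean squared prediction error in response
units, and the relative RMSPE expresses it as a percentage of the mean
observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricSet:
    """Bundle of CV statistics for one pooled prediction vector.

    ``r2`` is NaN (with ``r2_defined`` False) when either vector is
    constant, where the Pearson correlation does not exist; it is never
    silently reported as 0.
    """

    r2: float
    rmspe: float
    relative_rmspe_pct: float
    n: int

    @property
    def r2_defined(self) -> bool:
        return not np.isnan(self.r2)


def _validate_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("observed and predicted must be finite")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observations and predictions.

    Returns NaN when either vector is constant (correlation undefined).
    Invariant under positive affine transforms of either argument.
    """
    obs, pred = _validate_pair(observed, predicted)
    if obs.size < 3:
        raise ValueError("r_squared requires at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return float("nan")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def rmspe(observed, predicted) -> float:
    """Root mean squared prediction error, in response units."""
    obs, pred = _validate_pair(observed, predicted)
    if obs.size == 0:
        raise ValueError("rmspe requires at least one pair")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def relative_rmspe(observed, predicted) -> float:
    """RMSPE as a percentage of the mean observed value."""
    obs, pred = _validate_pair(observed, predicted)
    mean_obs = obs.mean()
    if mean_obs == 0:
        raise ValueError("relative RMSPE undefined for zero mean observed value")
    return float(100.0 * rmspe(obs, pred) / mean_obs)


def metric_set(observed, predicted) -> MetricSet:
    """Compute the full metric bundle on one pooled prediction vector."""
    obs, pred = _validate_pair(observed, predicted)
    return MetricSet(
        r2=r_squared(obs, pred) if obs.size >= 3 else float("nan"),
        rmspe=rmspe(obs, pred),
        relative_rmspe_pct=(
            relative_rmspe(obs, pred) if obs.mean() != 0 else float("nan")
        ),
        n=int(obs.size),
    )
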