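"""Quality-control exclusion chain for reference pixels.

Reference biomass pixels derived from field inventories are screened
before modeling: sufficient vegetation cover at the start of the study
period, enough field plots per pixel for a representative estimate, no
substantial forest loss or fire during the imaging period, and no gross
spectral outliers.  Stages run in that order; each reports its removals
as a percentage of the set it received, so the audit trail reads like the
provenance section of a mapping study.

Boundary semantics are taken literally from the stated rules: cover
"less than 89%" is removed (ties kept), "fewer than 3" plots removed,
loss "greater than 5%" removed (ties kept), any "nonnull" fire removed,
spectral values "more than 10 SD" from the band mean removed (mean/SD
computed once on the stage input — a single pass, not iterated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .synthetic import SampleSet


@dataclass(frozen=True)
class FilterStage:
    name: str
    threshold: dict
    n_removed: int
    pct_of_input: float


@dataclass(frozen=True)
class FilterReport:
    """Ordered per-stage audit of the exclusion chain."""

    stages: tuple[FilterStage, ...]
    n_in: int
    n_out: int

    def __post_init__(self):
        if self.n_out != self.n_in - sum(s.n_removed for s in self.stages):
            raise ValueError("stage removals do not sum to n_in - n_out")

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _require(sample_set: SampleSet, columns: list[str], stage: str) -> None:
    missing = [c for c in columns if c not in sample_set.frame.columns]
    if missing:
        raise ValueError(f"filter stage {stage!r} requires columns {missing}")


def _keep(sample_set: SampleSet, mask: np.ndarray) -> SampleSet:
    return SampleSet(sample_set.frame.loc[mask].copy(),
                     qc_columns=sample_set.qc_columns,
                     provenance=sample_set.provenance,
                     allow_duplicate_coordinates=True)


def filter_forest_cover(sample_set: SampleSet,
                        min_cover_pct: float = 89.0) -> SampleSet:
    """Remove pixels with vegetation cover below ``min_cover_pct``."""
    _require(sample_set, ["forest_cover_pct"], "forest_cover")
    mask = sample_set.frame["forest_cover_pct"].to_numpy(dtype=float) >= min_cover_pct
    return _keep(sample_set, mask)


def filter_plot_count(sample_set: SampleSet, min_plots: int = 3) -> SampleSet:
    """Remove pixels containing fewer than ``min_plots`` field plots."""
    _require(sample_set, ["plot_count"], "plot_count")
    mask = sample_set.frame["plot_count"].to_numpy(dtype=float) >= min_plots
    return _keep(sample_set, mask)


def filter_disturbance(sample_set: SampleSet, max_loss_pct: float = 5.0,
                       max_fire_pct: float = 0.0) -> SampleSet:
    """Remove pixels with forest loss > ``max_loss_pct`` OR fire > ``max_fire_pct``."""
    _require(sample_set, ["forest_loss_pct", "fire_pct"], "disturbance")
    loss = sample_set.frame["forest_loss_pct"].to_numpy(dtype=float)
    fire = sample_set.frame["fire_pct"].to_numpy(dtype=float)
    mask = ~((loss > max_loss_pct) | (fire > max_fire_pct))
    return _keep(sample_set, mask)


def filter_spectral_outliers(sample_set: SampleSet, bands: list[str],
                             k_sd: float = 10.0) -> SampleSet:
    """Remove pixels whose value in any band is > ``k_sd`` SDs from the band mean.

    Means and SDs come from the stage's input set in a single pass.  A
    zero-variance band cannot flag outliers and imposes no removals.
    """
    _require(sample_set, list(bands), "spectral_outliers")
    if len(sample_set) < 2:
        raise ValueError("spectral outlier screening needs at least 2 rows")
    mask = np.ones(len(sample_set), dtype=bool)
    for band in bands:
        vals = sample_set.frame[band].to_numpy(dtype=float)
        sd = vals.std()
        if sd == 0:
            continue
        mask &= np.abs(vals - vals.mean()) <= k_sd * sd
    return _keep(sample_set, mask)


@dataclass(frozen=True)
class FilterConfig:
    """Stage toggles and thresholds for :func:`apply_filters`."""

    min_cover_pct: float = 89.0
    min_plots: int = 3
    max_loss_pct: float = 5.0
    max_fire_pct: float = 0.0
    outlier_bands: tuple[str, ...] = ()
    outlier_k_sd: float = 10.0
    enabled: tuple[str, ...] = field(
        default=("forest_cover", "plot_count", "disturbance", "spectral_outliers")
    )


_STAGE_ORDER = ("forest_cover", "plot_count", "disturbance", "spectral_outliers")


def apply_filters(sample_set: SampleSet,
                  config: FilterConfig | None = None) -> tuple[SampleSet, FilterReport]:
    """Run the exclusion chain in canonical order and report per-stage removals.

    Percentages are relative to each stage's input (the running filtered
    set), matching how mapping studies report their exclusions.
    """
    config = config or FilterConfig()
    unknown = set(config.enabled) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown filter stages: {sorted(unknown)}")
    current = sample_set
    stages = []
    for name in _STAGE_ORDER:
        if name not in config.enabled:
            continue
        n_before = len(current)
        if name == "forest_cover":
            current = filter_forest_cover(current, config.min_cover_pct)
            threshold = {"min_cover_pct": config.min_cover_pct}
        elif name == "plot_count":
            current = filter_plot_count(current, config.min_plots)
            threshold = {"min_plots": config.min_plots}
        elif name == "disturbance":
            current = filter_disturbance(current, config.max_loss_pct,
                                         config.max_fire_pct)
            threshold = {"max_loss_pct": config.max_loss_pct,
                         "max_fire_pct": config.max_fire_pct}
        else:
            if not config.outlier_bands:
                continue
            current = filter_spectral_outliers(current,
                                               list(config.outlier_bands),
                                               config.outlier_k_sd)
            threshold = {"bands": list(config.outlier_bands),
                         "k_sd": config.outlier_k_sd}
        removed = n_before - len(current)
        stages.append(FilterStage(
            name=name,
            threshold=threshold,
            n_removed=removed,
            pct_of_input=100.0 * removed / n_before if n_before else 0.0,
        ))
    report = FilterReport(stages=tuple(stages), n_in=len(sample_set),
                          n_out=len(current))
    return current, report
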