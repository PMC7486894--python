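"""Derived climate and spectral covariates for biomass-mapping models.

Implements the water-balance and seasonality layers commonly derived from
monthly climatologies — annual water availability (cumulative P over PET),
monthly water deficit (P − PET), dry-season length and severity, the
maximal climatological water deficit (MCWD), and seasonality statistics —
plus the EVI2 and NDII spectral vegetation indices computed from surface
reflectance composites.

All monthly inputs are 12-element calendar climatologies.  Dry-season run
statistics treat the year as circular (a dry season straddling the
Dec→Jan boundary is one season), which matters for equatorial bimodal
climates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MONTHS = 12


def _monthly(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (MONTHS,):
        raise ValueError(f"{name} must have exactly {MONTHS} monthly values")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class DrySeasonStats:
    """Lengths (months) and severities (positive mm) of dry seasons.

    ``long_*`` refer to the longest circular run of dry months (deficit
    < 0); ``cumu_*`` pool all dry months of the year.  ``sr_*`` / ``wp_*``
    summarize solar radiation and water vapor pressure over the longest
    run, when those series are supplied.
    """

    long_length: int
    cumu_length: int
    long_severity: float
    cumu_severity: float
    sr_mean: float = float("nan")
    sr_max: float = float("nan")
    wp_mean: float = float("nan")
    wp_max: float = float("nan")


def water_availability(p, pet) -> float:
    """Annual water availability: ratio of cumulative P to cumulative PET."""
    p = _monthly(p, "P")
    pet = _monthly(pet, "PET")
    if np.any(p < 0) or np.any(pet < 0):
        raise ValueError("P and PET must be non-negative")
    total_pet = pet.sum()
    if total_pet == 0:
        raise ValueError("cumulative PET is zero; water availability undefined")
    return float(p.sum() / total_pet)


def monthly_deficit(p, pet) -> np.ndarray:
    """Monthly water deficit, P − PET (mm); negative months are dry."""
    return _monthly(p, "P") - _monthly(pet, "PET")


def _circular_runs(dry: np.ndarray) -> list[list[int]]:
    """Maximal runs of consecutive dry months on the circular calendar."""
    if dry.all():
        return [list(range(MONTHS))]
    if not dry.any():
        return []
    # rotate so the year starts on a wet month, then take linear runs
    start = int(np.argmin(dry))  # first False
    order = [(start + i) % MONTHS for i in range(MONTHS)]
    runs, current = [], []
    for m in order:
        if dry[m]:
            current.append(m)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def dry_season_stats(deficit, p=None, sr=None, wp=None) -> DrySeasonStats:
    """Dry-season lengths and severities from the monthly deficit.

    Dry months have deficit < 0.  The longest season is the longest
    circular run (ties broken by greater severity); severities are
    reported as positive magnitudes of the summed deficit.
    """
    d = _monthly(deficit, "deficit")
    dry = d < 0
    runs = _circular_runs(dry)
    cumu_length = int(dry.sum())
    cumu_severity = float(-d[dry].sum()) if cumu_length else 0.0
    if not runs:
        return DrySeasonStats(0, 0, 0.0, 0.0)
    # longest run; ties by severity
    best = max(runs, key=lambda r: (len(r), -d[r].sum()))
    long_severity = float(-d[best].sum())
    sr_arr = _monthly(sr, "SR") if sr is not None else None
    wp_arr = _monthly(wp, "WP") if wp is not None else None
    return DrySeasonStats(
        long_length=len(best),
        cumu_length=cumu_length,
        long_severity=long_severity,
        cumu_severity=cumu_severity,
        sr_mean=float(sr_arr[best].mean()) if sr_arr is not None else float("nan"),
        sr_max=float(sr_arr[best].max()) if sr_arr is not None else float("nan"),
        wp_mean=float(wp_arr[best].mean()) if wp_arr is not None else float("nan"),
        wp_max=float(wp_arr[best].max()) if wp_arr is not None else float("nan"),
    )


def mcwd(p, pet, max_cycles: int = 24) -> float:
    """Maximal climatological water deficit (mm, ≤ 0).

    Iterates the running balance WDₙ = min(0, WDₙ₋₁ + Pₙ − PETₙ) around
    the circular calendar until it reaches a fixed point (two cycles
    suffice unless every month is in deficit), then returns the most
    negative balance of the final cycle.  Under this circular iteration
    the result does not depend on which calendar month the dry season
    happens to start in.
    """
    deficit = monthly_deficit(p, pet)
    wd = 0.0
    final = np.zeros(MONTHS)
    prev_end = None
    first_cycle_min = 0.0
    for cycle in range(max_cycles):
        for m in range(MONTHS):
            wd = min(0.0, wd + deficit[m])
            final[m] = wd
        if cycle == 0:
            first_cycle_min = float(final.min())
        if wd == prev_end:
            return float(final.min())
        prev_end = wd
    # no fixed point: the balance drifts down every cycle (annual deficit
    # with no sustaining wet season); report one year's accumulation from
    # a saturated start, the standard annual-deficit convention
    return first_cycle_min


def seasonality(values, mode: str = "sd") -> float:
    """Seasonality of a monthly climatology.

    ``sd``: population standard deviation over the 12 months (the months
    are the full population of the climatology, not a sample).  ``cv``:
    coefficient of variation, 100·SD/mean.
    """
    v = _monthly(values, "values")
    sd = float(np.std(v))  # population SD (ddof=0)
    if mode == "sd":
        return sd
    if mode == "cv":
        mean = float(v.mean())
        if mean == 0:
            raise ValueError("CV undefined for zero mean")
        return 100.0 * sd / mean
    raise ValueError(f"unknown seasonality mode {mode!r}")


def temperature_seasonality(t) -> float:
    """Temperature seasonality reported as SD·100 (bioclim convention)."""
    return 100.0 * seasonality(t, "sd")


def evi2(red, nir):
    """Two-band enhanced vegetation index: 2.5·(NIR−RED)/(NIR+2.4·RED+1)."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if not (np.isfinite(red).all() and np.isfinite(nir).all()):
        raise ValueError("reflectances must be finite")
    denom = nir + 2.4 * red + 1.0
    if np.any(denom == 0):
        raise ValueError("EVI2 denominator is zero")
    out = 2.5 * (nir - red) / denom
    return float(out) if out.ndim == 0 else out


def ndii(nir, swir):
    """Normalized difference infrared index: (NIR−SWIR)/(NIR+SWIR).

    SWIR defaults to the ~1.6 µm band (SWIR1) by convention; any SWIR band
    may be passed.
    """
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if not (np.isfinite(nir).all() and np.isfinite(swir).all()):
        raise ValueError("reflectances must be finite")
    denom = nir + swir
    if np.any(denom == 0):
        raise ValueError("NDII denominator is zero")
    out = (nir - swir) / denom
    return float(out) if out.ndim == 0 else out


def derive_climate_columns(frame, prefix_p: str = "P", prefix_pet: str = "PET",
                           prefix_t: str = "T", prefix_sr: str = "SR",
                           prefix_wp: str = "WP"):
    """Append derived climate covariates to a table of monthly columns.

    Expects 12-column groups named like ``P01..P12``; T/SR/WP groups are
    optional and enable the corresponding derived layers.  Returns a new
    DataFrame with WA, CWD, dry-season and seasonality columns appended.
    """
    import pandas as pd

    def group(prefix):
        cols = [f"{prefix}{m:02d}" for m in range(1, 13)]
        return cols if all(c in frame.columns for c in cols) else None

    p_cols, pet_cols = group(prefix_p), group(prefix_pet)
    if p_cols is None or pet_cols is None:
        raise ValueError("monthly P01..P12 and PET01..PET12 columns required")
    t_cols, sr_cols, wp_cols = group(prefix_t), group(prefix_sr), group(prefix_wp)

    out = frame.copy()
    rows = []
    for _, row in frame.iterrows():
        p = row[p_cols].to_numpy(dtype=float)
        pet = row[pet_cols].to_numpy(dtype=float)
        d = monthly_deficit(p, pet)
        stats = dry_season_stats(
            d,
            sr=row[sr_cols].to_numpy(dtype=float) if sr_cols else None,
            wp=row[wp_cols].to_numpy(dtype=float) if wp_cols else None,
        )
        rec = {
            "WA": water_availability(p, pet),
            "CWD": mcwd(p, pet),
            "DS_long_length": stats.long_length,
            "DS_cumu_length": stats.cumu_length,
            "DS_long_sever": stats.long_severity,
            "DS_cumu_sever": stats.cumu_severity,
            "Prec_seaso": seasonality(p, "cv"),
        }
        if t_cols:
            rec["T_seaso"] = temperature_seasonality(row[t_cols].to_numpy(dtype=float))
        if sr_cols:
            rec["SolRad_sd"] = seasonality(row[sr_cols].to_numpy(dtype=float), "sd")
            rec["SolRad_DS_m"] = stats.sr_mean
            rec["SolRad_DS_max"] = stats.sr_max
        if wp_cols:
            rec["Vapor_sd"] = seasonality(row[wp_cols].to_numpy(dtype=float), "sd")
            rec["Vapor_DS_m"] = stats.wp_mean
            rec["Vapor_DS_max"] = stats.wp_max
        rows.append(rec)
    derived = pd.DataFrame(rows, index=frame.index)
    return pd.concat([out, derived], axis=1)
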