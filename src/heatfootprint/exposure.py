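"""WBGT heat-stress fields and heatwave detection.

The wet bulb globe temperature is approximated from air temperature and
relative humidity alone (solar radiation and wind terms are dropped, as is
standard for global-scale work):

    WBGT_outdoor = 0.567 * T_a + 3.94 + 0.393 * E
    E = RH/100 * 6.105 * exp(17.27 * T_a / (237.7 + T_a))     [hPa]
    WBGT_indoor  = WBGT_outdoor - 4

Heatwaves are runs of at least ``min_run`` consecutive days with daily
mean temperature strictly above a per-cell percentile threshold. The
benchmark definition uses the 95th percentile of a fixed baseline window
with runs of >= 2 days; a dynamic variant recomputes the threshold per
target year over the expanding window ending the year before (a crude
acclimatisation proxy); a stricter sensitivity preset uses the 97.5th
percentile with >= 4-day runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "INDOOR_OFFSET",
    "HeatwaveDefinition",
    "HeatwaveStats",
    "vapour_term",
    "wbgt_outdoor",
    "wbgt_indoor",
    "daily_triplet",
    "static_threshold",
    "detect_heatwaves",
    "dynamic_threshold",
    "detect_heatwaves_dynamic",
]

INDOOR_OFFSET = 4.0  # degC-WBGT radiation-exposure deduction


def vapour_term(t_a, rh):
    """Water vapour pressure E in hPa from temperature (degC) and RH (%)."""
    t_a = np.asarray(t_a, float)
    rh = np.asarray(rh, float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("RH must lie in [0, 100]")
    if np.any(~np.isfinite(t_a)) or np.any(t_a <= -237.7):
        raise ValueError("T_a must be finite and above -237.7 degC")
    return rh / 100.0 * 6.105 * np.exp(17.27 * t_a / (237.7 + t_a))


def wbgt_outdoor(t_a, rh):
    """Simplified outdoor WBGT (degC-WBGT)."""
    return 0.567 * np.asarray(t_a, float) + 3.94 + 0.393 * vapour_term(t_a, rh)


def wbgt_indoor(wbgt_out):
    """Indoor WBGT: outdoor value minus the fixed radiation offset."""
    return np.asarray(wbgt_out, float) - INDOOR_OFFSET


def daily_triplet(climate: xr.Dataset, indoor: bool = False) -> xr.Dataset:
    """Daily WBGT triplet (mean / max / half) from a climate dataset.

    Uses tmean and tmax with the same daily RH; wbgt_half is the midpoint
    of the other two. With ``indoor`` the fixed offset is subtracted from
    all three.
    """
    for v in ("tmean", "tmax", "rh"):
        if v not in climate:
            raise ValueError(f"climate dataset lacks variable {v!r}")
    if climate.tmean.shape != climate.tmax.shape:
        raise ValueError("tmean and tmax grids are inconsistent")
    if np.any(climate.tmax.values < climate.tmean.values):
        raise ValueError("tmax must be >= tmean")
    w_mean = wbgt_outdoor(climate.tmean.values, climate.rh.values)
    w_max = wbgt_outdoor(climate.tmax.values, climate.rh.values)
    if indoor:
        w_mean = wbgt_indoor(w_mean)
        w_max = wbgt_indoor(w_max)
    dims = climate.tmean.dims
    return xr.Dataset(
        {
            "wbgt_mean": (dims, w_mean),
            "wbgt_max": (dims, w_max),
            "wbgt_half": (dims, (w_mean + w_max) / 2.0),
        },
        coords=climate.tmean.coords,
    )


@dataclass
class HeatwaveDefinition:
    percentile: float = 95.0
    min_run: int = 2
    baseline_years: tuple[int, int] = (1985, 2015)
    dynamic: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")

    @classmethod
    def sensitivity(cls, **kw) -> "HeatwaveDefinition":
        """Stricter preset: 97.5th percentile, runs of >= 4 days."""
        kw.setdefault("percentile", 97.5)
        kw.setdefault("min_run", 4)
        return cls(**kw)


@dataclass
class HeatwaveStats:
    """Boolean event mask per cell-day and heatwave-day counts per cell-year."""

    mask: xr.DataArray  # bool (time, ...)
    hwn: xr.DataArray  # int (year, ...)


def static_threshold(tmean: xr.DataArray, percentile: float = 95.0,
                     baseline_years: tuple[int, int] | None = None) -> xr.DataArray:
    """Per-cell empirical percentile of baseline daily mean temperatures.

    Linear interpolation between closest order statistics (numpy default).
    """
    da = tmean
    if baseline_years is not None:
        y = da["time"].dt.year
        da = da.sel(time=(y >= baseline_years[0]) & (y <= baseline_years[1]))
    if da.sizes.get("time", 0) == 0:
        raise ValueError("empty baseline window")
    thr = np.percentile(da.values, percentile, axis=da.dims.index("time"))
    other = [d for d in da.dims if d != "time"]
    return xr.DataArray(thr, coords={d: da[d] for d in other}, dims=other)


def _run_mask(exceed: np.ndarray, min_run: int) -> np.ndarray:
    """Days belonging to runs of >= min_run consecutive exceedances.

    exceed: boolean array with time on axis 0.
    """
    flat = exceed.reshape(exceed.shape[0], -1)
    out = np.zeros_like(flat)
    n_t = flat.shape[0]
    for c in range(flat.shape[1]):
        col = flat[:, c]
        padded = np.concatenate(([False], col, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                out[s:e, c] = True
    return out.reshape(exceed.shape)


def detect_heatwaves(
    tmean: xr.DataArray,
    threshold: xr.DataArray | float,
    min_run: int = 2,
) -> HeatwaveStats:
    """Detect heatwave days against a static per-cell threshold.

    A day is a heatwave day iff it lies in a maximal run of >= min_run
    consecutive days with tmean strictly above the threshold. Runs that
    cross calendar-year boundaries contribute each day to its own year.
    """
    thr = threshold.values if isinstance(threshold, xr.DataArray) else threshold
    exceed = tmean.values > thr
    mask_np = _run_mask(exceed, min_run)
    mask = xr.DataArray(mask_np, coords=tmean.coords, dims=tmean.dims)
    hwn = _annual_counts(mask)
    return HeatwaveStats(mask=mask, hwn=hwn)


def _annual_counts(mask: xr.DataArray) -> xr.DataArray:
    grouped = mask.astype(np.int64).groupby("time.year").sum("time")
    return grouped


def dynamic_threshold(
    tmean: xr.DataArray,
    target_year: int,
    percentile: float = 95.0,
    history_start: int | None = None,
) -> xr.DataArray:
    """Expanding-window percentile threshold for one target year.

    Uses all days from ``history_start`` (default: first year present)
    through ``target_year - 1``; the target year's own data are never used.
    """
    years = tmean["time"].dt.year
    start = int(years.min()) if history_start is None else history_start
    if target_year <= start:
        raise ValueError("target year must be after the history start")
    return static_threshold(tmean, percentile, baseline_years=(start, target_year - 1))


def detect_heatwaves_dynamic(
    tmean: xr.DataArray,
    definition: HeatwaveDefinition,
    target_years: list[int] | None = None,
    history_start: int | None = None,
) -> HeatwaveStats:
    """Detect heatwaves with a per-target-year expanding-window threshold.

    Each target year is scanned against its own threshold; runs are
    evaluated within the year (with the preceding and following Dec/Jan
    context truncated at year edges, matching annual reporting).
    """
    years_all = tmean["time"].dt.year.values
    start = int(years_all.min()) if history_start is None else history_start
    if target_years is None:
        target_years = [int(y) for y in np.unique(years_all) if y > start]
    masks = []
    for y in target_years:
        thr = dynamic_threshold(tmean, y, definition.percentile, history_start=start)
        sub = tmean.sel(time=tmean["time"].dt.year == y)
        stats = detect_heatwaves(sub, thr, definition.min_run)
        masks.append(stats.mask)
    mask = xr.concat(masks, dim="time")
    return HeatwaveStats(mask=mask, hwn=_annual_counts(mask))
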