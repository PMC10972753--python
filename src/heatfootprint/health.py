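"""Heatwave excess mortality and its monetization.

Excess deaths in a cell-year follow the attributable-fraction form

    D_hw = POP * MR * (RR - 1) * HWN

with POP the cell population, MR the baseline daily all-cause mortality
rate, RR the climate-zone relative risk of mortality on heatwave days and
HWN the number of heatwave days. Deaths are valued with a value of
statistical life (VSL) anchored on a US estimate and scaled across regions
by income with a configurable elasticity; an equal-valuation variant
applies the population-weighted world mean VSL everywhere.

Relative risks by climate zone and the zone map itself are configuration
inputs. The packaged defaults are illustrative placeholders, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DEFAULT_RR_TABLE",
    "VSLParams",
    "excess_deaths",
    "zone_map_from_climate",
    "deaths_by_region",
    "vsl_for_region",
    "vsl_table",
    "health_loss_value",
]

#: Illustrative relative risks by climate zone (1 = coolest, 4 = hottest).
#: Placeholder values for running the pipeline end to end; real analyses
#: must supply epidemiologically estimated RRs per zone.
DEFAULT_RR_TABLE = {1: 1.05, 2: 1.07, 3: 1.10, 4: 1.14}

US_ANCHOR_INCOME = 65_000.0  # USD/yr per capita, anchor economy


@dataclass
class VSLParams:
    anchor_vsl: float = 11_000_000.0  # USD (2019)
    anchor_income_pc: float = US_ANCHOR_INCOME
    income_elasticity: float = 1.0
    mode: str = "income_scaled"  # or "equal_world"
    deflator: float = 1.0  # e.g. 2019 -> 2020 USD

    def __post_init__(self) -> None:
        if self.anchor_vsl <= 0:
            raise ValueError("anchor_vsl must be positive")
        if self.income_elasticity < 0:
            raise ValueError("income elasticity must be >= 0")
        if self.mode not in ("income_scaled", "equal_world"):
            raise ValueError("mode must be 'income_scaled' or 'equal_world'")


def excess_deaths(pop, mr, rr, hwn):
    """Excess deaths POP * MR * (RR - 1) * HWN, elementwise."""
    pop = np.asarray(pop, float)
    mr = np.asarray(mr, float)
    rr = np.asarray(rr, float)
    hwn = np.asarray(hwn, float)
    if np.any(pop < 0) or np.any(mr < 0) or np.any(hwn < 0):
        raise ValueError("POP, MR and HWN must be nonnegative")
    if np.any(rr < 1):
        raise ValueError("RR must be >= 1 (heatwaves assumed non-protective)")
    return pop * mr * (rr - 1.0) * hwn


def zone_map_from_climate(
    tmean: xr.DataArray, n_zones: int = 4
) -> xr.DataArray:
    """Assign climate zones by quantiles of warm-season mean temperature.

    A reproducible stand-in for an externally supplied zone map: cells are
    binned into ``n_zones`` groups (1 = coolest quartile ... 4 = hottest)
    by their mean temperature over each hemisphere's warm season.
    """
    from .labour import warm_season_mask

    window = warm_season_mask(tmean["time"], tmean["lat"])
    warm_mean = tmean.where(window).mean("time")
    vals = warm_mean.values
    qs = np.quantile(vals, np.linspace(0, 1, n_zones + 1)[1:-1])
    zones = np.digitize(vals, qs) + 1
    return xr.DataArray(zones, coords=warm_mean.coords, dims=warm_mean.dims)


def deaths_by_region(
    population: xr.DataArray,
    region_id: xr.DataArray,
    region_names: list[str],
    mortality_rate: pd.Series,
    zone_map: xr.DataArray,
    rr_table: dict[int, float],
    hwn: xr.DataArray,
) -> pd.DataFrame:
    """Aggregate cell-level excess deaths to regions, per year.

    mortality_rate is indexed by region (daily per-capita). Returns a
    DataFrame indexed by year with one column per region.
    """
    rr_cells = np.vectorize(lambda z: rr_table[int(z)])(zone_map.values)
    mr_cells = mortality_rate.to_numpy(float)[region_id.values]
    out = {}
    for y in hwn["year"].values:
        d = excess_deaths(
            population.values, mr_cells, rr_cells, hwn.sel(year=y).values
        )
        out[int(y)] = [
            float(d[region_id.values == r].sum()) for r in range(len(region_names))
        ]
    return pd.DataFrame.from_dict(
        out, orient="index", columns=region_names
    ).rename_axis("year")


def vsl_for_region(
    income_pc: float, params: VSLParams
) -> float:
    """Income-scaled VSL: anchor * (income / anchor_income) ** elasticity."""
    if income_pc <= 0:
        raise ValueError("income must be positive")
    return (
        params.anchor_vsl
        * (income_pc / params.anchor_income_pc) ** params.income_elasticity
        * params.deflator
    )


def vsl_table(
    income_pc: pd.Series, population: pd.Series, params: VSLParams
) -> pd.Series:
    """Per-region VSL under the configured valuation mode.

    equal_world applies one common value: the population-weighted mean of
    the income-scaled VSLs.
    """
    scaled = income_pc.map(lambda v: vsl_for_region(v, params))
    if params.mode == "equal_world":
        pop = population.reindex(scaled.index).to_numpy(float)
        common = float(np.average(scaled.to_numpy(float), weights=pop))
        return pd.Series(common, index=scaled.index, name="vsl")
    return scaled.rename("vsl")


def health_loss_value(
    deaths: pd.Series, vsl: pd.Series, gdp: pd.Series
) -> pd.DataFrame:
    """Monetized health loss per region, absolute and as share of GDP."""
    for other in (vsl, gdp):
        if not deaths.index.equals(other.index):
            raise ValueError("region sets of deaths, VSL and GDP must match")
    loss = deaths * vsl
    return pd.DataFrame(
        {
            "deaths": deaths,
            "loss_usd": loss,
            "loss_pct_gdp": 100.0 * loss / gdp,
        }
    )
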