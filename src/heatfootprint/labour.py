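"""Work-capacity loss from WBGT and aggregation to labour shocks.

Two exposure-response curves map WBGT to the lost share of work capacity
for a given metabolic intensity (200/300/400 W):

* the benchmark error-function curve,
      loss = 1/2 * (1 + erf((WBGT - Prod_mean) / (Prod_SD * sqrt(2)))),
  i.e. the Gaussian CDF with the stated mean and SD; and
* the Hothaps logistic workability curve,
      workability = 0.1 + 0.9 / (1 + (WBGT / alpha1)**alpha2),
  used as a sensitivity alternative (loss = 1 - workability).

Daily impact uses the 4+4+4 approximation of a 12 h workday: four hours
each near WBGT_max, WBGT_mean, and their midpoint. Indoor workers are
partially protected by air conditioning, with penetration rising with
income and with the indoor-WBGT climatology. Cell losses are population-
weighted into per region-sector daily unavailable labour shares
gamma^L(t), which are nonzero only inside each hemisphere's warm season
(June-September in the north, December-March in the south).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import erf as _erf, expit as _expit

from . import exposure

__all__ = [
    "WorkIntensity",
    "DEFAULT_INTENSITIES",
    "DEFAULT_SECTOR_INTENSITY",
    "ACModel",
    "loss_fraction_erf",
    "workability_hothaps",
    "daily_loss",
    "ac_penetration",
    "effective_daily_loss",
    "warm_season_mask",
    "aggregate_gamma",
]


@dataclass
class WorkIntensity:
    """Exposure-response parameters for one metabolic work-intensity class.

    prod_mean / prod_sd parameterize the erf curve (degC-WBGT); alpha1 /
    alpha2 the Hothaps curve. Defaults below are configuration, not
    estimates; override them from a parameter file for real analyses.
    """

    level: int  # W
    setting: str  # "indoor" | "outdoor"
    prod_mean: float
    prod_sd: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if self.setting not in ("indoor", "outdoor"):
            raise ValueError("setting must be 'indoor' or 'outdoor'")
        if self.prod_sd <= 0 or self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("prod_sd, alpha1, alpha2 must be positive")


#: Illustrative parameter defaults per intensity class. The Hothaps alphas
#: are the published Hothaps-programme fits; the erf mean/SD values are
#: round placeholders of the right order and must be replaced with the
#: estimates appropriate to the study population.
DEFAULT_INTENSITIES = {
    200: WorkIntensity(200, "indoor", prod_mean=34.0, prod_sd=2.0,
                       alpha1=34.64, alpha2=22.72),
    300: WorkIntensity(300, "indoor", prod_mean=32.0, prod_sd=2.0,
                       alpha1=32.93, alpha2=17.81),
    400: WorkIntensity(400, "outdoor", prod_mean=30.0, prod_sd=2.0,
                       alpha1=30.94, alpha2=16.64),
}

#: Default sector -> intensity-class assignment.
DEFAULT_SECTOR_INTENSITY = {
    "services": 200,
    "industry": 300,
    "construction": 400,
    "agriculture": 400,
}


def sector_intensity(sector: str) -> WorkIntensity:
    """Intensity class for a sector (unknown sectors default to 300 W indoor)."""
    return DEFAULT_INTENSITIES[DEFAULT_SECTOR_INTENSITY.get(sector, 300)]


def loss_fraction_erf(wbgt, prod_mean: float, prod_sd: float):
    """Benchmark exposure curve: Gaussian CDF of WBGT at (mean, SD)."""
    if prod_sd <= 0:
        raise ValueError("prod_sd must be positive")
    z = (np.asarray(wbgt, float) - prod_mean) / (prod_sd * np.sqrt(2.0))
    return 0.5 * (1.0 + _erf(z))


def workability_hothaps(wbgt, alpha1: float, alpha2: float):
    """Hothaps logistic workability in (0.1, 1.0]; 1 at WBGT = 0."""
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("alpha1 and alpha2 must be positive")
    wbgt = np.asarray(wbgt, float)
    if np.any(wbgt < 0):
        raise ValueError("WBGT must be nonnegative for the Hothaps curve")
    return 0.1 + 0.9 / (1.0 + (wbgt / alpha1) ** alpha2)


def daily_loss(
    triplet: xr.Dataset, intensity: WorkIntensity, function: str = "erf"
):
    """Daily lost work-capacity share via the 4+4+4 rule.

    Unweighted mean of the pointwise loss at wbgt_max, wbgt_mean and
    wbgt_half (4 h each of a 12 h day). ``triplet`` must already be on the
    indoor scale for indoor intensity classes (see exposure.daily_triplet).
    """
    if function == "erf":
        f = lambda w: loss_fraction_erf(w, intensity.prod_mean, intensity.prod_sd)
    elif function == "hothaps":
        f = lambda w: 1.0 - workability_hothaps(
            np.maximum(np.asarray(w, float), 0.0), intensity.alpha1, intensity.alpha2
        )
    else:
        raise ValueError(f"unknown exposure function {function!r}")
    parts = [f(triplet[v].values) for v in ("wbgt_max", "wbgt_mean", "wbgt_half")]
    out = sum(parts) / 3.0
    return xr.DataArray(out, coords=triplet["wbgt_mean"].coords,
                        dims=triplet["wbgt_mean"].dims)


@dataclass
class ACModel:
    """Air-conditioning penetration from income and heat climatology.

    penetration = saturation(climatology) * logistic(slope * (log income -
    log income_midpoint)), where saturation is itself a logistic in the
    indoor-WBGT climatology rising from ~0 in cool climates toward
    max_penetration in hot ones. A stand-in functional form: nondecreasing
    in both arguments, bounded in [0, max_penetration].
    """

    max_penetration: float = 1.0
    climatology_midpoint: float = 18.0  # degC-WBGT, indoor warm-season mean
    climatology_slope: float = 0.35  # per degC-WBGT
    income_midpoint: float = 15_000.0  # USD/yr
    income_slope: float = 1.5  # per log-income unit

    def __post_init__(self) -> None:
        if not (0 <= self.max_penetration <= 1):
            raise ValueError("max_penetration must lie in [0, 1]")
        if self.climatology_slope < 0 or self.income_slope < 0:
            raise ValueError("slopes must be nonnegative")

    def saturation(self, indoor_wbgt_climatology) -> np.ndarray:
        c = np.asarray(indoor_wbgt_climatology, float)
        return self.max_penetration * _expit(
            self.climatology_slope * (c - self.climatology_midpoint)
        )


def ac_penetration(income_pc, indoor_wbgt_climatology, model: ACModel):
    """AC penetration in [0, 1], nondecreasing in income and climatology."""
    income = np.asarray(income_pc, float)
    if np.any(income <= 0):
        raise ValueError("income must be positive")
    sat = model.saturation(indoor_wbgt_climatology)
    inc = _expit(model.income_slope * (np.log(income) - np.log(model.income_midpoint)))
    return sat * inc


def effective_daily_loss(loss, setting: str, penetration):
    """AC protection: indoor losses scaled by (1 - penetration); outdoor unchanged."""
    loss = np.asarray(loss, float)
    pen = np.asarray(penetration, float)
    if np.any((loss < 0) | (loss > 1)) or np.any((pen < 0) | (pen > 1)):
        raise ValueError("loss and penetration must lie in [0, 1]")
    if setting == "indoor":
        return (1.0 - pen) * loss
    if setting == "outdoor":
        return loss + 0.0
    raise ValueError("setting must be 'indoor' or 'outdoor'")


def warm_season_mask(time: xr.DataArray, lat: xr.DataArray) -> xr.DataArray:
    """Boolean (time, lat) mask of each hemisphere's warm season.

    June 1 - September 30 north of the equator, December 1 - March 30
    south of it; cells within one degree of the equator follow the
    northern window (a documented convention).
    """
    month = time.dt.month
    day = time.dt.day
    north = (month >= 6) & (month <= 9)
    south = (month == 12) | (month <= 2) | ((month == 3) & (day <= 30))
    is_north = lat > -1.0
    return xr.where(is_north, north, south).transpose(time.dims[0], lat.dims[0])


def aggregate_gamma(
    climate: xr.Dataset,
    population: xr.DataArray,
    region_id: xr.DataArray,
    region_names: list[str],
    sectors: list[str],
    income_pc: pd.Series | None = None,
    ac_model: ACModel | None = None,
    function: str = "erf",
) -> pd.DataFrame:
    """Per region-sector daily unavailable labour share gamma^L(t).

    Population-weighted mean of the effective daily loss over each
    region's cells, for each sector's intensity class, zeroed outside the
    warm-season window. Returns a DataFrame indexed by time with a
    (region, sector) column MultiIndex.
    """
    pop = population.values.astype(float)
    rid = region_id.values
    n_regions = len(region_names)
    if any(pop[rid == r].sum() <= 0 for r in range(n_regions)):
        raise ValueError("every region must contain population")

    trip_out = exposure.daily_triplet(climate, indoor=False)
    trip_in = exposure.daily_triplet(climate, indoor=True)

    window = warm_season_mask(climate["time"], climate["lat"]).values  # (t, lat)
    window3 = window[:, :, None]  # broadcast over lon

    if ac_model is not None and income_pc is not None:
        clim = trip_in["wbgt_mean"].where(
            xr.DataArray(
                np.broadcast_to(window3, trip_in["wbgt_mean"].shape),
                coords=trip_in["wbgt_mean"].coords,
            )
        ).mean("time").values
        income_cells = income_pc.to_numpy(float)[rid]
        pen = ac_penetration(income_cells, clim, ac_model)
    else:
        pen = np.zeros_like(pop)

    out = {}
    for sector in sectors:
        inten = sector_intensity(sector)
        trip = trip_in if inten.setting == "indoor" else trip_out
        cell_loss = daily_loss(trip, inten, function=function).values  # (t, lat, lon)
        eff = effective_daily_loss(cell_loss, inten.setting, pen[None, :, :])
        eff = np.where(window3, eff, 0.0)
        for r, rname in enumerate(region_names):
            sel = rid == r
            w = pop[sel]
            gamma = (eff[:, sel] * w).sum(axis=1) / w.sum()
            out[(rname, sector)] = gamma

    df = pd.DataFrame(out, index=pd.Index(climate["time"].values, name="time"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["region", "sector"])
    return df
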