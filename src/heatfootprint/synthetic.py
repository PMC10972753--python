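"""Synthetic inputs for the heat-footprint pipeline.

Generates the four input families the analysis needs — gridded daily
climate, gridded population with region tables, balanced multiregional
input-output (MRIO) tables, and warming scenarios — with the statistical
structure the downstream modules assume: seasonal temperature cycles with
AR(1) daily anomalies and a linear secular warming trend, humidity
co-varying with the temperature anomaly, spatially clustered population,
and MRIO tables satisfying both row and column balance.

All generators are pure functions of (config, seed): identical configs
yield bit-identical output. A 365-day no-leap calendar is used so that a
noise-free, trend-free climate repeats exactly year over year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .ario import MRIOTable

__all__ = [
    "ClimateGenConfig",
    "MRIOGenConfig",
    "PopulationGenConfig",
    "PopulationData",
    "generate_climate",
    "generate_mrio",
    "generate_population",
    "generate_scenario",
    "SCENARIO_WARMING_RATES",
    "noleap_time_index",
    "write_climate",
    "read_climate",
    "largest_remainder_round",
]

DEFAULT_SECTORS = ["agriculture", "industry", "services", "construction"]


def _sector_names(n: int) -> list[str]:
    if n <= len(DEFAULT_SECTORS):
        return DEFAULT_SECTORS[:n]
    return DEFAULT_SECTORS + [f"sector{k:02d}" for k in range(len(DEFAULT_SECTORS), n)]


def noleap_time_index(start_year: int, end_year: int) -> pd.DatetimeIndex:
    """Daily datetime index from Jan 1 start_year to Dec 31 end_year, Feb 29 removed."""
    idx = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    return idx[~((idx.month == 2) & (idx.day == 29))]


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


@dataclass
class ClimateGenConfig:
    """Configuration for the gridded daily climate generator.

    base_temp is the per-cell annual-mean temperature in degC (scalar or
    (n_lat, n_lon) array). noise_sd is the AR(1) innovation standard
    deviation; the stationary anomaly has sd noise_sd / sqrt(1 - rho^2) but
    its lag-1 autocorrelation equals ar1_rho either way. warming_rate is in
    degC per decade. rh_temp_coupling couples relative humidity to the
    daily temperature anomaly (% per degC; typically negative). Grid cells
    are 0.5-degree centres placed symmetrically about the equator.
    """

    n_lat: int = 6
    n_lon: int = 8
    start_year: int = 2000
    end_year: int = 2010
    base_temp: float | np.ndarray = 22.0
    seasonal_amplitude: float = 8.0
    ar1_rho: float = 0.7
    noise_sd: float = 2.0
    warming_rate: float = 0.0
    rh_mean: float = 60.0
    rh_temp_coupling: float = -1.5
    diurnal_range: float = 6.0
    lat_step: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        vals = [
            self.seasonal_amplitude,
            self.ar1_rho,
            self.noise_sd,
            self.warming_rate,
            self.rh_mean,
            self.rh_temp_coupling,
            self.diurnal_range,
        ]
        if not np.all(np.isfinite(np.asarray(self.base_temp, float))):
            raise ValueError("base_temp must be finite")
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("climate config values must be finite")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must be at least 1x1")


def _grid_coords(n_lat: int, n_lon: int, lat_step: float) -> tuple[np.ndarray, np.ndarray]:
    lat = (np.arange(n_lat) - (n_lat - 1) / 2.0) * lat_step
    lon = (np.arange(n_lon) - (n_lon - 1) / 2.0) * lat_step
    return lat, lon


def generate_climate(config: ClimateGenConfig) -> xr.Dataset:
    """Generate daily tmean, tmax and rh on a lat x lon grid.

    The seasonal cycle peaks in mid-July for northern-hemisphere cells and
    mid-January for southern ones (equatorial cells follow the north).
    tmax = tmean + diurnal_range, so tmax >= tmean everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lat, lon = _grid_coords(config.n_lat, config.n_lon, config.lat_step)
    times = noleap_time_index(config.start_year, config.end_year)
    n_t = len(times)

    doy = times.dayofyear.to_numpy().astype(float)
    # no-leap doy: shift post-Feb days in leap years back by one
    leap = times.year.values % 4 == 0
    post = (times.month.values > 2) & leap
    doy = doy - post.astype(float)

    peak = np.where(lat >= 0, 196.0, 15.0)  # mid-July / mid-January
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy[:, None] - peak[None, :]) / 365.0
    )  # (t, lat)

    # AR(1) anomalies per cell
    anom = np.zeros((n_t, config.n_lat, config.n_lon))
    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=(n_t, config.n_lat, config.n_lon))
        rho = config.ar1_rho
        anom[0] = eps[0] / np.sqrt(1 - rho**2)
        for t in range(1, n_t):
            anom[t] = rho * anom[t - 1] + eps[t]

    years_elapsed = (times.year.values - config.start_year) + (doy - 1) / 365.0
    trend = config.warming_rate * years_elapsed / 10.0  # (t,)

    base = np.broadcast_to(
        np.asarray(config.base_temp, float), (config.n_lat, config.n_lon)
    )
    tmean = (
        base[None, :, :]
        + seasonal[:, :, None]
        + anom
        + trend[:, None, None]
    )
    tmax = tmean + config.diurnal_range
    rh = np.clip(config.rh_mean + config.rh_temp_coupling * anom, 0.0, 100.0)

    return xr.Dataset(
        {
            "tmean": (("time", "lat", "lon"), tmean),
            "tmax": (("time", "lat", "lon"), tmax),
            "rh": (("time", "lat", "lon"), rh),
        },
        coords={"time": times, "lat": lat, "lon": lon},
        attrs={"warming_rate": config.warming_rate, "seed": config.seed},
    )


SCENARIO_WARMING_RATES = {"low": 0.1, "mid": 0.3, "high": 0.6}  # degC / decade


def generate_scenario(label: str, base: ClimateGenConfig) -> ClimateGenConfig:
    """Return ``base`` with the warming rate of a named scenario.

    Labels are deliberately neutral (low / mid / high) rather than claiming
    fidelity to specific emission pathways; warming rates increase strictly
    across the three labels.
    """
    if label not in SCENARIO_WARMING_RATES:
        raise KeyError(
            f"unknown scenario {label!r}; choose from {sorted(SCENARIO_WARMING_RATES)}"
        )
    return replace(base, warming_rate=SCENARIO_WARMING_RATES[label])


def write_climate(ds: xr.Dataset, path: str | Path) -> None:
    ds.to_netcdf(path, engine="scipy")


def read_climate(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


# ---------------------------------------------------------------------------
# MRIO
# ---------------------------------------------------------------------------


@dataclass
class MRIOGenConfig:
    n_regions: int = 5
    n_sectors: int = 4
    flow_density: float = 0.8
    va_share_range: tuple[float, float] = (0.25, 0.45)
    final_share_range: tuple[float, float] = (0.2, 0.35)
    scale: float = 1000.0  # monetary units per year per firm (median output)
    home_bias: float = 3.0  # final-demand preference for the home region
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.va_share_range, self.final_share_range):
            if not (0 < lo <= hi < 1):
                raise ValueError("share ranges must satisfy 0 < lo <= hi < 1")
        if self.va_share_range[1] + self.final_share_range[1] >= 0.95:
            raise ValueError(
                "va and final-demand share ranges leave too little room "
                "for intermediate flows"
            )
        if not (0 < self.flow_density <= 1):
            raise ValueError("flow_density must lie in (0, 1]")
        if self.n_regions < 1 or self.n_sectors < 1:
            raise ValueError("need at least one region and one sector")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _ipf_balance(
    Z0: np.ndarray,
    row_totals: np.ndarray,
    col_totals: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> np.ndarray:
    """Iterative proportional fitting of Z0 to prescribed margins."""
    Z = Z0.copy()
    for _ in range(max_iter):
        rs = Z.sum(axis=1)
        Z *= (row_totals / np.where(rs > 0, rs, 1.0))[:, None]
        cs = Z.sum(axis=0)
        Z *= (col_totals / np.where(cs > 0, cs, 1.0))[None, :]
        rres = np.max(np.abs(Z.sum(axis=1) - row_totals) / row_totals)
        cres = np.max(np.abs(Z.sum(axis=0) - col_totals) / col_totals)
        if max(rres, cres) < tol:
            return Z
    raise RuntimeError(
        f"IPF did not converge (residual {max(rres, cres):.2e}); "
        "the sampled zero pattern cannot support the margins"
    )


def generate_mrio(config: MRIOGenConfig) -> MRIOTable:
    """Generate a balanced synthetic MRIO table.

    Gross outputs, value-added shares and final-demand shares are sampled,
    final demand is rescaled so that total value added equals total final
    demand (the GDP identity that makes row and column margins consistent),
    and the intermediate-flow matrix is balanced to the implied margins by
    iterative proportional fitting. Both balance identities hold to better
    than 1e-8 relative.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = [f"R{r:02d}" for r in range(config.n_regions)]
    sectors = _sector_names(config.n_sectors)
    firms = pd.MultiIndex.from_product(
        [regions, sectors], names=["region", "sector"]
    )
    n = len(firms)

    x = config.scale * rng.lognormal(0.0, 0.4, size=n)
    va_share = rng.uniform(*config.va_share_range, size=n)
    va = va_share * x

    f = rng.uniform(*config.final_share_range, size=n) * x
    f *= va.sum() / f.sum()  # GDP identity: total final demand = total VA
    # keep intermediate row totals positive: cap final demand per firm
    cap = 0.9 * (x - va)
    for _ in range(100):
        over = f > cap
        if not over.any():
            break
        excess = (f[over] - cap[over]).sum()
        f[over] = cap[over]
        headroom = cap[~over] - f[~over]
        f[~over] += excess * headroom / headroom.sum()
    else:
        raise ValueError("could not place final demand within firm headroom")

    row_totals = x - f
    col_totals = x - va

    mask = rng.random((n, n)) < config.flow_density
    np.fill_diagonal(mask, True)  # guarantees feasible support
    Z0 = rng.uniform(0.5, 1.5, size=(n, n)) * mask
    Z = _ipf_balance(Z0, row_totals, col_totals)

    # split final demand across region households with home bias
    hh_w = rng.uniform(0.5, 1.5, size=(n, config.n_regions))
    home = np.array([regions.index(r) for r in firms.get_level_values("region")])
    hh_w[np.arange(n), home] *= 1.0 + config.home_bias
    F = f[:, None] * hh_w / hh_w.sum(axis=1, keepdims=True)

    return MRIOTable(
        Z=pd.DataFrame(Z, index=firms, columns=firms),
        final_demand=pd.DataFrame(F, index=firms, columns=regions),
        value_added=pd.Series(va, index=firms, name="value_added"),
        gross_output=pd.Series(x, index=firms, name="gross_output"),
    )


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass
class PopulationGenConfig:
    """Gridded population plus per-region mortality and income tables.

    clustering controls spatial concentration: 0 gives a near-uniform
    field, larger values concentrate people in fewer cells (the weight
    field is exp(clustering * smooth noise)). mortality_rate is the
    baseline daily all-cause rate (deaths per person per day); income_pc
    is annual income per capita in USD. Scalars are broadcast to all
    regions; sequences must have length n_regions. Regions partition the
    grid into contiguous longitude bands.
    """

    n_lat: int = 6
    n_lon: int = 8
    n_regions: int = 4
    total_pop: int = 10_000_000
    clustering: float = 1.0
    mortality_rate: float | tuple = 2.2e-5
    income_pc: float | tuple = 20_000.0
    seed: int = 0

    def validate(self) -> None:
        if self.total_pop < 0:
            raise ValueError("total_pop must be >= 0")
        if self.clustering < 0:
            raise ValueError("clustering must be >= 0")
        if self.n_regions < 1 or self.n_regions > self.n_lon:
            raise ValueError("need 1 <= n_regions <= n_lon")
        mr = np.atleast_1d(np.asarray(self.mortality_rate, float))
        if np.any((mr <= 0) | (mr >= 1)):
            raise ValueError("mortality rates must lie in (0, 1)")
        inc = np.atleast_1d(np.asarray(self.income_pc, float))
        if np.any(inc <= 0):
            raise ValueError("incomes must be positive")


@dataclass
class PopulationData:
    grid: xr.Dataset  # population (lat, lon), region_id (lat, lon)
    regions: pd.DataFrame  # index region, cols mortality_rate, income_pc

    @property
    def region_names(self) -> list[str]:
        return list(self.regions.index)


def largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(np.int64)
    short = int(total - counts.sum())
    if short > 0:
        frac = quota - counts
        top = np.argsort(frac, kind="stable")[::-1][:short]
        counts[top] += 1
    return counts


def _smooth_field(rng: np.random.Generator, n_lat: int, n_lon: int) -> np.ndarray:
    """Low-pass filtered unit-variance noise (separable gaussian smoothing)."""
    from scipy.ndimage import gaussian_filter

    g = gaussian_filter(
        rng.standard_normal((n_lat, n_lon)),
        sigma=max(1.0, min(n_lat, n_lon) / 6.0),
        mode="wrap",
    )
    sd = g.std()
    return g / sd if sd > 0 else g


def generate_population(config: PopulationGenConfig) -> PopulationData:
    config.validate()
    rng = np.random.default_rng(config.seed)
    lat, lon = _grid_coords(config.n_lat, config.n_lon, 0.5)

    field_ = _smooth_field(rng, config.n_lat, config.n_lon)
    weights = np.exp(config.clustering * field_)
    pop = largest_remainder_round(weights.ravel(), config.total_pop).reshape(
        config.n_lat, config.n_lon
    )

    # contiguous longitude bands as regions
    band = np.minimum(
        (np.arange(config.n_lon) * config.n_regions) // config.n_lon,
        config.n_regions - 1,
    )
    region_id = np.broadcast_to(band, (config.n_lat, config.n_lon)).copy()
    region_names = [f"R{r:02d}" for r in range(config.n_regions)]

    def _per_region(v) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(v, float))
        if arr.size == 1:
            return np.full(config.n_regions, arr[0])
        if arr.size != config.n_regions:
            raise ValueError("per-region values must have length n_regions")
        return arr

    regions = pd.DataFrame(
        {
            "mortality_rate": _per_region(config.mortality_rate),
            "income_pc": _per_region(config.income_pc),
        },
        index=pd.Index(region_names, name="region"),
    )

    grid = xr.Dataset(
        {
            "population": (("lat", "lon"), pop),
            "region_id": (("lat", "lon"), region_id),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"region_names": ",".join(region_names)},  # netCDF3-safe scalar
    )
    return PopulationData(grid=grid, regions=regions)


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------


def config_to_yaml(config, path: str | Path) -> None:
    d = asdict(config)
    d["__class__"] = type(config).__name__
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d))


_CONFIG_CLASSES = {
    "ClimateGenConfig": ClimateGenConfig,
    "MRIOGenConfig": MRIOGenConfig,
    "PopulationGenConfig": PopulationGenConfig,
}


def config_from_yaml(path: str | Path):
    d = yaml.safe_load(Path(path).read_text())
    cls = _CONFIG_CLASSES[d.pop("__class__")]
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)
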