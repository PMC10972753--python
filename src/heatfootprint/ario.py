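"""Adaptive input-output (ARIO-style) supply-chain shock propagation.

Firms are (region, sector) pairs calibrated from a balanced multiregional
input-output (MRIO) table; each region has one representative household.
Production follows a Leontief technology constrained by labour, capital and
intermediate inventories; scarce output is rationed proportionally to
orders; firms reorder to refill inventories toward a target cover, choosing
among suppliers of the same product class by capacity-weighted baseline
shares (which is what lets clients substitute across regions).

Losses are accounted as time-integrated value-added shortfalls:

    TEF = va_bar * T - sum_t va_a(t)      (total economic footprint)
    DEF = va_bar * T - sum_t va_max(t)    (direct, from capacity limits)
    PEF = TEF - DEF                       (propagated through the network)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MRIOTable",
    "CalibratedNetwork",
    "SimConfig",
    "SimState",
    "ShockSeries",
    "FootprintResult",
    "calibrate",
    "capacity_labour",
    "capacity_capital",
    "capacity_inventory",
    "max_capacity",
    "actual_production",
    "allocate",
    "restore_inventory",
    "issue_orders_firm",
    "issue_orders_household",
    "step",
    "run",
]


# ---------------------------------------------------------------------------
# MRIO container
# ---------------------------------------------------------------------------


@dataclass
class MRIOTable:
    """Balanced region x sector flow table (annual, monetary units).

    Z : intermediate flows, rows = supplying firm, columns = purchasing firm.
    final_demand : firm x region-household final purchases.
    value_added : per-firm primary inputs.
    gross_output : per-firm gross output x.

    Balance identities (both must hold for a valid table):
        row:    x_i = sum_j Z[i, j] + sum_h F[i, h]
        column: x_i = sum_p Z[p, i] + va_i
    """

    Z: pd.DataFrame
    final_demand: pd.DataFrame
    value_added: pd.Series
    gross_output: pd.Series

    def __post_init__(self) -> None:
        firms = self.Z.index
        if not (
            self.Z.columns.equals(firms)
            and self.final_demand.index.equals(firms)
            and self.value_added.index.equals(firms)
            and self.gross_output.index.equals(firms)
        ):
            raise ValueError("MRIOTable blocks must share one firm index")

    @property
    def firms(self) -> pd.MultiIndex:
        return self.Z.index

    @property
    def regions(self) -> list:
        return list(self.final_demand.columns)

    @property
    def sectors(self) -> list:
        return list(dict.fromkeys(self.firms.get_level_values("sector")))

    def balance_residuals(self) -> tuple[float, float]:
        """Max relative row and column balance residuals."""
        x = self.gross_output.to_numpy(float)
        row = self.Z.sum(axis=1).to_numpy() + self.final_demand.sum(axis=1).to_numpy()
        col = self.Z.sum(axis=0).to_numpy() + self.value_added.to_numpy()
        scale = np.maximum(np.abs(x), 1e-300)
        return (
            float(np.max(np.abs(row - x) / scale)),
            float(np.max(np.abs(col - x) / scale)),
        )

    def to_dir(self, path: str | Path) -> None:
        """Write long-format CSVs: flows.csv, final_demand.csv, va.csv."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        n = len(self.firms)
        reg = self.firms.get_level_values("region").to_numpy()
        sec = self.firms.get_level_values("sector").to_numpy()
        long = pd.DataFrame(
            {
                "origin_region": np.repeat(reg, n),
                "origin_sector": np.repeat(sec, n),
                "dest_region": np.tile(reg, n),
                "dest_sector": np.tile(sec, n),
                "flow": self.Z.to_numpy().ravel(),
            }
        )
        long.to_csv(path / "flows.csv", index=False)
        hh = np.asarray(self.final_demand.columns)
        fd = pd.DataFrame(
            {
                "origin_region": np.repeat(reg, len(hh)),
                "origin_sector": np.repeat(sec, len(hh)),
                "dest_region": np.tile(hh, n),
                "flow": self.final_demand.to_numpy().ravel(),
            }
        )
        fd.to_csv(path / "final_demand.csv", index=False)
        va = pd.DataFrame(
            {"region": reg, "sector": sec, "value_added": self.value_added.to_numpy()}
        )
        va.to_csv(path / "va.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "MRIOTable":
        path = Path(path)
        long = pd.read_csv(path / "flows.csv")
        Z = long.pivot_table(
            index=["origin_region", "origin_sector"],
            columns=["dest_region", "dest_sector"],
            values="flow",
            fill_value=0.0,
            sort=False,
        )
        Z.index.names = ["region", "sector"]
        Z.columns.names = ["region", "sector"]
        Z = Z.reindex(columns=Z.index, fill_value=0.0)
        fd = pd.read_csv(path / "final_demand.csv")
        F = fd.pivot_table(
            index=["origin_region", "origin_sector"],
            columns="dest_region",
            values="flow",
            fill_value=0.0,
            sort=False,
        ).reindex(Z.index, fill_value=0.0)
        F.index.names = ["region", "sector"]
        va = pd.read_csv(path / "va.csv").set_index(["region", "sector"])[
            "value_added"
        ]
        va = va.reindex(Z.index).fillna(0.0)
        x = Z.sum(axis=1) + F.sum(axis=1)
        return cls(Z=Z, final_demand=F, value_added=va, gross_output=x)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibratedNetwork:
    """Per-step equilibrium benchmark derived from an annual MRIO table.

    Product classes coincide with sectors: firm j supplies product class
    ``sector(j)``. All flow quantities are per simulation step (annual
    values divided by ``steps_per_year``), so ``va_bar * T`` over a
    one-year horizon equals annual value added.
    """

    firms: pd.MultiIndex
    regions: list
    sectors: list
    sector_of: np.ndarray  # (n,) product-class index of each firm
    x_bar: np.ndarray  # (n,) per-step equilibrium output
    a: np.ndarray  # (n, P) input coefficients a_i^p
    b: np.ndarray  # (n,) value-added coefficients
    va_bar: np.ndarray  # (n,) per-step equilibrium value added
    fod_bar: np.ndarray  # (n, n) baseline firm orders, [supplier j, client i]
    hod_bar: np.ndarray  # (n, H) baseline household orders
    steps_per_year: int
    product_of_firm: np.ndarray = field(init=False)  # alias of sector_of

    def __post_init__(self) -> None:
        self.product_of_firm = self.sector_of
        # indicator M[p, j] = 1 if firm j produces product p
        P = len(self.sectors)
        n = len(self.x_bar)
        self.product_matrix = np.zeros((P, n))
        self.product_matrix[self.sector_of, np.arange(n)] = 1.0

    @property
    def n_firms(self) -> int:
        return len(self.x_bar)

    @property
    def n_households(self) -> int:
        return self.hod_bar.shape[1]

    def baseline_household_demand(self) -> np.ndarray:
        """HD_bar[h, q]: baseline household demand by product class."""
        return (self.product_matrix @ self.hod_bar).T


def calibrate(mrio: MRIOTable, steps_per_year: int = 365) -> CalibratedNetwork:
    """Derive coefficients and baseline orders from a balanced MRIO table.

    Raises ``ValueError`` on unbalanced tables (relative residual > 1e-6)
    or zero-output firms.
    """
    r_row, r_col = mrio.balance_residuals()
    if max(r_row, r_col) > 1e-6:
        raise ValueError(
            f"MRIO table unbalanced: residuals row={r_row:.2e} col={r_col:.2e}"
        )
    x_annual = mrio.gross_output.to_numpy(float)
    if np.any(x_annual <= 0):
        raise ValueError("all firms must have positive gross output")

    firms = mrio.firms
    sectors = mrio.sectors
    sec_idx = {s: k for k, s in enumerate(sectors)}
    sector_of = np.array([sec_idx[s] for s in firms.get_level_values("sector")])

    Z = mrio.Z.to_numpy(float) / steps_per_year  # [supplier, client]
    F = mrio.final_demand.to_numpy(float) / steps_per_year
    va = mrio.value_added.to_numpy(float) / steps_per_year
    x = x_annual / steps_per_year

    P = len(sectors)
    n = len(x)
    M = np.zeros((P, n))
    M[sector_of, np.arange(n)] = 1.0
    z_by_product = M @ Z  # (P, clients): input of product p into client i
    a = (z_by_product / x[None, :]).T  # (n, P)
    b = va / x

    return CalibratedNetwork(
        firms=firms,
        regions=mrio.regions,
        sectors=sectors,
        sector_of=sector_of,
        x_bar=x,
        a=a,
        b=b,
        va_bar=va,
        fod_bar=Z.copy(),
        hod_bar=F.copy(),
        steps_per_year=steps_per_year,
    )


# ---------------------------------------------------------------------------
# Simulation configuration / state
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    horizon: int = 365
    inventory_target: float = 15.0  # n_i^p, steps of cover
    overproduction: float = 1.0  # multiplier on max capacity (>= 1)
    substitution_exponent: float = 1.0  # 0 = fixed baseline shares
    drift_tol: float = 1e-6  # non-finite / sanity guard

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.inventory_target < 0:
            raise ValueError("inventory target must be >= 0")
        if self.overproduction < 1:
            raise ValueError("overproduction factor must be >= 1")
        if self.substitution_exponent < 0:
            raise ValueError("substitution exponent must be >= 0")


@dataclass
class SimState:
    t: int
    S: np.ndarray  # (n, P) inventories
    fod_prev: np.ndarray  # (n, n) orders received last step [supplier, client]
    hod_prev: np.ndarray  # (n, H)
    x_a_prev: np.ndarray  # (n,)

    def copy(self) -> "SimState":
        return SimState(
            self.t,
            self.S.copy(),
            self.fod_prev.copy(),
            self.hod_prev.copy(),
            self.x_a_prev.copy(),
        )


@dataclass
class ShockSeries:
    """Exogenous shock trajectories over the simulation horizon.

    gamma_L, gamma_K : (T, n) unavailable shares in [0, 1].
    household_demand : (T, H, P) exogenous final demand, or None for
        baseline demand throughout.
    """

    gamma_L: np.ndarray
    gamma_K: np.ndarray | None = None
    household_demand: np.ndarray | None = None

    @classmethod
    def none(cls, horizon: int, n_firms: int) -> "ShockSeries":
        return cls(gamma_L=np.zeros((horizon, n_firms)))

    def validate(self, horizon: int, n_firms: int) -> None:
        for name, g in (("gamma_L", self.gamma_L), ("gamma_K", self.gamma_K)):
            if g is None:
                continue
            if g.shape != (horizon, n_firms):
                raise ValueError(f"{name} must have shape (horizon, n_firms)")
            if np.any(~np.isfinite(g)) or g.min() < 0 or g.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def capacity_labour(gamma_L: np.ndarray, x_bar: np.ndarray) -> np.ndarray:
    """x^L = (1 - gamma^L) * x_bar."""
    return (1.0 - gamma_L) * x_bar


def capacity_capital(gamma_K: np.ndarray, x_bar: np.ndarray) -> np.ndarray:
    """x^K = (1 - gamma^K) * x_bar."""
    return (1.0 - gamma_K) * x_bar


def capacity_inventory(S: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-product supportable output x^p = S^p / a^p.

    Products a firm does not use (a^p = 0) impose no constraint (+inf).
    """
    if np.any(S < 0):
        raise ValueError("negative inventory")
    with np.errstate(divide="ignore", invalid="ignore"):
        xp = np.where(a > 0, S / np.where(a > 0, a, 1.0), np.inf)
    return xp


def max_capacity(
    x_L: np.ndarray,
    x_K: np.ndarray,
    x_p: np.ndarray,
    overproduction: float = 1.0,
) -> np.ndarray:
    """Elementwise min of all capacity constraints, times overproduction."""
    cap = np.minimum(np.minimum(x_L, x_K), x_p.min(axis=1))
    return overproduction * cap


def actual_production(x_max: np.ndarray, tod_prev: np.ndarray) -> np.ndarray:
    """x^a = min(x^max, total orders received last step)."""
    return np.minimum(x_max, tod_prev)


def allocate(
    x_a: np.ndarray, fod: np.ndarray, hod: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Proportional rationing of each supplier's output across its orders.

    Returns (FRC, HRC) with sum over clients == x_a per supplier (exactly
    zero allocations for suppliers with zero total orders).
    """
    total = fod.sum(axis=1) + hod.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    ratio = np.where(total > 0, x_a / safe, 0.0)
    return fod * ratio[:, None], hod * ratio[:, None]


def restore_inventory(
    S: np.ndarray,
    used: np.ndarray,
    frc: np.ndarray,
    product_matrix: np.ndarray,
) -> np.ndarray:
    """S(t) = S(t-1) - used + receipts, receipts pooled by product class."""
    restored = (product_matrix @ frc).T  # (clients, P)
    return S - used + restored


def _weighted_order_split(
    totals: np.ndarray,
    baseline: np.ndarray,
    utilisation: np.ndarray,
    product_matrix: np.ndarray,
    exponent: float,
) -> np.ndarray:
    """Split per-(client, product) order totals across candidate suppliers.

    Weight of supplier j for client c is baseline[j, c] times the
    supplier's capacity utilisation (x_a / x_bar) raised to ``exponent``;
    with every supplier at baseline capacity the split reduces exactly to
    baseline shares. If every candidate supplier has zero capacity the
    split falls back to baseline shares. Suppliers with zero baseline flow
    never receive orders.

    totals : (n_clients, P); baseline : (n_suppliers, n_clients).
    Returns orders with the same shape as baseline.
    """
    with np.errstate(invalid="ignore"):
        capw = np.power(utilisation, exponent)  # 0**0 == 1: fixed shares
    W = baseline * capw[:, None]
    denom = product_matrix @ W  # (P, clients)
    denom_base = product_matrix @ baseline
    use_fallback = (denom <= 0) & (denom_base > 0)
    denom_eff = np.where(use_fallback, denom_base, denom)
    # expand per-supplier: supplier j belongs to product row sector_of[j]
    sec = product_matrix.argmax(axis=0)  # (n_suppliers,)
    denom_j = denom_eff[sec, :]  # (n_suppliers, n_clients)
    W_eff = np.where(use_fallback[sec, :], baseline, W)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(denom_j > 0, W_eff / np.where(denom_j > 0, denom_j, 1.0), 0.0)
    return share * totals[:, sec].T


def issue_orders_firm(
    S: np.ndarray,
    S_target: np.ndarray,
    x_a: np.ndarray,
    net: CalibratedNetwork,
    exponent: float = 1.0,
) -> np.ndarray:
    """Orders FOD[j, i] issued by firm i to supplier j to close inventory gaps.

    The per-product order total is max(S* - S, 0); it is split across
    the suppliers of that product in proportion to baseline flow times
    supplier capacity utilisation (raised to ``exponent``), renormalised.
    """
    gap = np.maximum(S_target - S, 0.0)  # (n_clients, P)
    return _weighted_order_split(
        gap, net.fod_bar, x_a / net.x_bar, net.product_matrix, exponent
    )


def issue_orders_household(
    hd: np.ndarray,
    x_a: np.ndarray,
    net: CalibratedNetwork,
    exponent: float = 1.0,
) -> np.ndarray:
    """Orders HOD[j, h] from households, splitting HD_h^q across suppliers."""
    return _weighted_order_split(
        hd, net.hod_bar, x_a / net.x_bar, net.product_matrix, exponent
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def initial_state(net: CalibratedNetwork, config: SimConfig) -> SimState:
    S0 = config.inventory_target * net.a * net.x_bar[:, None]
    return SimState(
        t=0,
        S=S0,
        fod_prev=net.fod_bar.copy(),
        hod_prev=net.hod_bar.copy(),
        x_a_prev=net.x_bar.copy(),
    )


def step(
    state: SimState,
    net: CalibratedNetwork,
    gamma_L: np.ndarray,
    gamma_K: np.ndarray,
    hd: np.ndarray,
    config: SimConfig,
) -> tuple[SimState, np.ndarray, np.ndarray]:
    """One simulation step: produce -> allocate -> restore -> order.

    Orders are issued against the post-production, pre-delivery inventory
    position, so that replacing the step's own consumption is part of the
    inventory gap; this is what makes the unshocked economy an exact fixed
    point of the dynamics.

    Returns (next_state, x_a, x_max).
    """
    x_L = capacity_labour(gamma_L, net.x_bar)
    x_K = capacity_capital(gamma_K, net.x_bar)
    x_p = capacity_inventory(state.S, net.a)
    x_max = max_capacity(x_L, x_K, x_p, config.overproduction)

    tod_prev = state.fod_prev.sum(axis=1) + state.hod_prev.sum(axis=1)
    x_a = actual_production(x_max, tod_prev)

    frc, hrc = allocate(x_a, state.fod_prev, state.hod_prev)

    used = net.a * x_a[:, None]
    S_pre_delivery = state.S - used
    S_next = restore_inventory(state.S, used, frc, net.product_matrix)

    if not (np.all(np.isfinite(S_next)) and np.all(np.isfinite(x_a))):
        raise FloatingPointError(f"non-finite state at step {state.t}")

    S_target = config.inventory_target * net.a * x_max[:, None]
    fod = issue_orders_firm(
        S_pre_delivery, S_target, x_a, net, config.substitution_exponent
    )
    hod = issue_orders_household(hd, x_a, net, config.substitution_exponent)

    return (
        SimState(t=state.t + 1, S=S_next, fod_prev=fod, hod_prev=hod, x_a_prev=x_a),
        x_a,
        x_max,
    )


@dataclass
class FootprintResult:
    """Time-integrated value-added losses per firm plus step series."""

    firms: pd.MultiIndex
    regions: list
    tef: np.ndarray  # (n,)
    def_: np.ndarray  # (n,)
    pef: np.ndarray  # (n,)
    va_a: np.ndarray  # (T, n)
    va_max: np.ndarray  # (T, n)
    x_a: np.ndarray  # (T, n)
    horizon: int

    def per_firm(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"TEF": self.tef, "DEF": self.def_, "PEF": self.pef},
            index=self.firms,
        )

    def per_region(self) -> pd.DataFrame:
        return self.per_firm().groupby(level="region", sort=False).sum()

    def totals(self) -> dict[str, float]:
        return {
            "TEF": float(self.tef.sum()),
            "DEF": float(self.def_.sum()),
            "PEF": float(self.pef.sum()),
        }


def run(
    net: CalibratedNetwork,
    shocks: ShockSeries,
    config: SimConfig,
) -> FootprintResult:
    """Run the simulator over ``config.horizon`` steps and account losses."""
    T = config.horizon
    n = net.n_firms
    shocks.validate(T, n)
    gamma_K = (
        shocks.gamma_K if shocks.gamma_K is not None else np.zeros((T, n))
    )
    hd_base = net.baseline_household_demand()

    state = initial_state(net, config)
    va_a = np.empty((T, n))
    va_max = np.empty((T, n))
    x_a_series = np.empty((T, n))
    for t in range(T):
        hd = (
            shocks.household_demand[t]
            if shocks.household_demand is not None
            else hd_base
        )
        state, x_a, x_max = step(
            state, net, shocks.gamma_L[t], gamma_K[t], hd, config
        )
        va_a[t] = net.b * x_a
        va_max[t] = net.b * x_max
        x_a_series[t] = x_a

    tef = net.va_bar * T - va_a.sum(axis=0)
    def_ = net.va_bar * T - va_max.sum(axis=0)
    return FootprintResult(
        firms=net.firms,
        regions=net.regions,
        tef=tef,
        def_=def_,
        pef=tef - def_,
        va_a=va_a,
        va_max=va_max,
        x_a=x_a_series,
        horizon=T,
    )
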