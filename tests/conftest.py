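import numpy as np
import pandas as pd
import pytest

import heatfootprint as hf
from heatfootprint import ario


@pytest.fixture(scope="session")
def mrio_2x2() -> ario.MRIOTable:
    return hf.generate_mrio(hf.MRIOGenConfig(n_regions=2, n_sectors=2, seed=1))


@pytest.fixture(scope="session")
def net_2x2(mrio_2x2) -> ario.CalibratedNetwork:
    return ario.calibrate(mrio_2x2, steps_per_year=365)


@pytest.fixture(scope="session")
def climate_small():
    """11 years of daily climate on a 4x4 grid straddling the equator."""
    cfg = hf.ClimateGenConfig(
        n_lat=4, n_lon=4, start_year=2000, end_year=2010, seed=7
    )
    return hf.generate_climate(cfg)


def chain_mrio() -> ario.MRIOTable:
    """Two-firm chain: A (upstream, no inputs) supplies B; both sell to
    households. Annual = per-step values when calibrated at 1 step/year."""
    firms = pd.MultiIndex.from_tuples(
        [("RA", "s1"), ("RB", "s2")], names=["region", "sector"]
    )
    Z = pd.DataFrame([[0.0, 60.0], [0.0, 0.0]], index=firms, columns=firms)
    F = pd.DataFrame(
        [[40.0, 0.0], [0.0, 90.0]], index=firms, columns=["RA", "RB"]
    )
    va = pd.Series([100.0, 30.0], index=firms)
    x = pd.Series([100.0, 90.0], index=firms)
    return ario.MRIOTable(Z=Z, final_demand=F, value_added=va, gross_output=x)


def isolated_mrio(output: float = 200.0) -> ario.MRIOTable:
    """Single firm with no intermediate use selling only to its household."""
    firms = pd.MultiIndex.from_tuples([("R0", "s0")], names=["region", "sector"])
    Z = pd.DataFrame([[0.0]], index=firms, columns=firms)
    F = pd.DataFrame([[output]], index=firms, columns=["R0"])
    va = pd.Series([output], index=firms)
    x = pd.Series([output], index=firms)
    return ario.MRIOTable(Z=Z, final_demand=F, value_added=va, gross_output=x)


def brute_force_heatwave_mask(series: np.ndarray, threshold: float, min_run: int):
    """Day-by-day scan oracle: mark runs of >= min_run days above threshold."""
    n = len(series)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if series[i] > threshold:
            j = i
            while j < n and series[j] > threshold:
                j += 1
            if j - i >= min_run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask
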