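"""Cigarette affordability: the relative income price (RIP) and price summaries.

The RIP expresses how expensive cigarettes are relative to local income: the
percentage of per-capita GDP needed to buy half a pack (10 cigarettes) a day
for a year, i.e. 182.5 packs of 20.  Higher RIP means less affordable.  Prices
and GDP are both in international dollars (I$), so the ratio is unit-free and
comparable across countries and years.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DomainError, EmptyInputError

#: packs of 20 consumed in a year at half a pack per day (365 / 2)
PACKS_PER_YEAR = 182.5


def compute_rip(price, gdp_pc):
    """Relative income price, in percentage points of per-capita GDP.

    Parameters
    ----------
    price : float or array-like
        Price of a 20-cigarette pack in I$.  NaN propagates (missing price
        gives missing RIP).
    gdp_pc : float or array-like
        Per-capita GDP in I$; must be strictly positive.

    Returns
    -------
    float or ndarray
        ``100 * price * 182.5 / gdp_pc``.
    """
    price_arr = np.asarray(price, dtype=float)
    gdp_arr = np.asarray(gdp_pc, dtype=float)
    if np.any(gdp_arr <= 0) or np.any(np.isnan(gdp_arr)):
        raise DomainError("gdp_pc must be strictly positive")
    if np.any(price_arr[~np.isnan(price_arr)] < 0):
        raise DomainError("price must be non-negative")
    rip = 100.0 * price_arr * PACKS_PER_YEAR / gdp_arr
    if rip.ndim == 0:
        return float(rip)
    return rip


def add_rip(policies: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a policy table with a ``rip`` column appended."""
    out = policies.copy()
    out["rip"] = compute_rip(out["price"].to_numpy(), out["gdp_pc"].to_numpy())
    return out


def weighted_mean_price(policies: pd.DataFrame, weights: Mapping[str, float] | pd.Series) -> float:
    """Population-weighted mean pack price over countries with a known price.

    ``policies`` needs columns ``country`` and ``price``; ``weights`` maps
    country to its population (aged 15+ by convention).  Countries with a
    missing price are dropped from both numerator and denominator.
    """
    w = pd.Series(weights, dtype=float)
    if (w <= 0).any():
        raise DomainError("weights must be strictly positive")
    prices = policies.set_index("country")["price"].astype(float)
    prices = prices.dropna()
    if prices.empty:
        raise EmptyInputError("no non-missing prices to average")
    common = prices.index.intersection(w.index)
    if common.empty:
        raise EmptyInputError("no countries shared between prices and weights")
    p, ww = prices.loc[common], w.loc[common]
    return float((p * ww).sum() / ww.sum())


def affordability_decline_share(
    rip_early: Mapping[str, float] | pd.Series,
    rip_late: Mapping[str, float] | pd.Series,
) -> float:
    """Percent of countries where cigarettes became less affordable.

    A country counts when its late-period RIP strictly exceeds its
    early-period RIP; ties count as no decline in affordability.  Only
    countries present in both inputs are compared.
    """
    early = pd.Series(rip_early, dtype=float).dropna()
    late = pd.Series(rip_late, dtype=float).dropna()
    common = early.index.intersection(late.index)
    if common.empty:
        raise EmptyInputError("no overlapping countries between the two RIP maps")
    increased = (late.loc[common] > early.loc[common]).sum()
    return 100.0 * float(increased) / len(common)
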