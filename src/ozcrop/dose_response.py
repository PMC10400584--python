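"""Linear AOT40 dose-response: exposure -> relative yield loss -> bushels -> USD.

Soybean relative yield loss (RYL) is linear in AOT40, RYL = a * AOT40
with a = 0.0113 per ppmV hr.  Converting RYL to bushels lost needs a
convention because reported production is what was actually harvested:

* ``"compensated"`` (default) treats observed production P as
  post-damage, so the unexposed potential was P / (1 - RYL) and the
  loss is P * RYL / (1 - RYL).
* ``"simple"`` applies RYL directly: loss = P * RYL.

The two agree to first order in RYL; compensated >= simple always.
Money is the bushel loss times a fixed per-bushel price, reported to
cent precision with all internal arithmetic in full float precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import CountySet

logger = logging.getLogger(__name__)

#: Soybean dose-response slope per (ppmV hr).
DEFAULT_A = 0.0113
#: U.S. soybean price per bushel (USD), 2020 marketing reference.
DEFAULT_PRICE_USD_PER_BU = 9.0075

#: Cap keeping RYL strictly below 1 so the compensated loss stays finite.
_RYL_CAP = 1.0 - 1e-9

LOSS_CONVENTIONS = ("compensated", "simple")


@dataclass(frozen=True)
class DoseResponseParams:
    a: float = DEFAULT_A
    loss_convention: str = "compensated"
    price_usd_per_bu: float = DEFAULT_PRICE_USD_PER_BU

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"dose-response slope a must be > 0, got {self.a}")
        if self.loss_convention not in LOSS_CONVENTIONS:
            raise ValueError(
                f"loss_convention must be one of {LOSS_CONVENTIONS}, got {self.loss_convention!r}"
            )
        if self.price_usd_per_bu < 0:
            raise ValueError(f"price must be >= 0, got {self.price_usd_per_bu}")


def relative_yield_loss(aot40, a: float = DEFAULT_A):
    """RYL = a * AOT40, capped strictly below 1 (cap events logged).

    Accepts scalars or arrays; returns the same shape.
    """
    arr = np.asarray(aot40, dtype=float)
    if (arr < 0).any():
        raise ValueError("AOT40 must be >= 0")
    if not a > 0:
        raise ValueError(f"a must be > 0, got {a}")
    ryl = a * arr
    n_capped = int((ryl > _RYL_CAP).sum())
    if n_capped:
        logger.warning(
            "relative yield loss capped at %.9f for %d value(s); exposures are "
            "outside the linear dose-response range",
            _RYL_CAP,
            n_capped,
        )
        ryl = np.minimum(ryl, _RYL_CAP)
    return float(ryl) if np.isscalar(aot40) else ryl


def production_loss_bu(production, ryl, convention: str = "compensated"):
    """Bushels lost given observed production and relative yield loss."""
    p = np.asarray(production, dtype=float)
    r = np.asarray(ryl, dtype=float)
    if (p < 0).any():
        raise ValueError("production must be >= 0")
    if (r < 0).any() or (r >= 1).any():
        raise ValueError("RYL must satisfy 0 <= RYL < 1")
    if convention == "compensated":
        loss = p * r / (1.0 - r)
    elif convention == "simple":
        loss = p * r
    else:
        raise ValueError(f"unknown loss convention {convention!r}")
    scalar = np.isscalar(production) and np.isscalar(ryl)
    return float(loss) if scalar else loss


def economic_loss_usd(loss_bu, price: float = DEFAULT_PRICE_USD_PER_BU):
    """USD value of a bushel loss (full precision; round for display)."""
    b = np.asarray(loss_bu, dtype=float)
    if (b < 0).any() or price < 0:
        raise ValueError("loss and price must be >= 0")
    out = b * price
    return float(out) if np.isscalar(loss_bu) else out


def compute_impacts(
    exposure_table: pd.DataFrame,
    counties: CountySet,
    params: DoseResponseParams = DoseResponseParams(),
) -> pd.DataFrame:
    """Join county exposures with production and apply the dose-response.

    Returns a CountyImpactTable with columns county_id, region, aot40,
    ryl, loss_bu, loss_usd.  Counties whose production is withheld
    ("combined counties") are dropped with a logged count before the
    loss computation; zero-production counties are retained and
    contribute zero loss.
    """
    prod = counties.production_frame()
    table = exposure_table.merge(prod, on="county_id", how="left", validate="one_to_one")
    withheld = table["production_bu"].isna()
    if withheld.any():
        logger.warning(
            "excluding %d county(ies) with withheld/combined production", int(withheld.sum())
        )
        table = table.loc[~withheld].reset_index(drop=True)
    ryl = relative_yield_loss(table["aot40"].to_numpy(), params.a)
    loss_bu = production_loss_bu(
        table["production_bu"].to_numpy(), ryl, params.loss_convention
    )
    return pd.DataFrame(
        {
            "county_id": table["county_id"],
            "region": table["region"],
            "aot40": table["aot40"],
            "ryl": ryl,
            "production_bu": table["production_bu"],
            "loss_bu": loss_bu,
            "loss_usd": economic_loss_usd(loss_bu, params.price_usd_per_bu),
        }
    )
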