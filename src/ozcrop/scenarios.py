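"""Scenario differencing and regional/domain-wide reporting.

The pipeline runs twice -- once per emissions scenario (e.g. a
business-as-usual counterfactual "BAU" and the realised "C19" case) --
and this module differences the two county impact tables (perturbed
minus baseline), summarises deltas by region, and assembles the
domain-wide bookkeeping: total losses per scenario, production-reduction
percentages, and the USD production gain attributed to the perturbation.

Money totals are computed by summing bushels per scenario first,
differencing, then multiplying by the price, so the printed gain is
exactly price x (bushel-total difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import REGIONS
from .dose_response import DEFAULT_PRICE_USD_PER_BU

_DELTA_FIELDS = ("aot40", "ryl", "loss_bu", "loss_usd")


def scenario_difference(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-county deltas, ``b - a`` for every numeric impact field.

    ``table_a`` is the reference scenario (e.g. BAU) and ``table_b`` the
    perturbed one (e.g. C19), so deltas follow the perturbed-minus-
    reference sign convention.  Both tables must cover exactly the same
    counties; a mismatch is rejected listing the symmetric difference.
    """
    ids_a, ids_b = set(table_a["county_id"]), set(table_b["county_id"])
    if ids_a != ids_b:
        diff = sorted(ids_a ^ ids_b)
        raise ValueError(f"county sets differ; symmetric difference: {diff}")
    a = table_a.set_index("county_id").sort_index()
    b = table_b.set_index("county_id").sort_index()
    out = pd.DataFrame(
        {
            "region": a["region"],
            "production_bu": a["production_bu"],
        }
    )
    for col in _DELTA_FIELDS:
        out[f"delta_{col}"] = b[col] - a[col]
    return out.reset_index()


def regional_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Per-region (min, max) of delta AOT40 and delta bushel loss.

    Regions whose counties all have zero production report the exposure
    range only (loss cells are NaN), mirroring regions that grow no
    soybeans.  An unlabelled or unknown region is rejected.
    """
    unknown = set(deltas["region"]) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region label(s): {sorted(unknown)}")
    rows = []
    for region, grp in deltas.groupby("region", sort=False):
        has_crop = (grp["production_bu"] > 0).any()
        rows.append(
            {
                "region": region,
                "delta_aot40_min": grp["delta_aot40"].min(),
                "delta_aot40_max": grp["delta_aot40"].max(),
                "delta_loss_bu_min": grp["delta_loss_bu"].min() if has_crop else np.nan,
                "delta_loss_bu_max": grp["delta_loss_bu"].max() if has_crop else np.nan,
                "n_counties": len(grp),
            }
        )
    order = {r: k for k, r in enumerate(REGIONS)}
    rows.sort(key=lambda r: order[r["region"]])
    return pd.DataFrame(rows)


def reduction_percent(total_loss_bu: float, reference_production_bu: float) -> float:
    """Production reduction as a percentage of a reference production."""
    if not reference_production_bu > 0:
        raise ValueError("reference production must be > 0")
    if total_loss_bu < 0:
        raise ValueError("total loss must be >= 0")
    return 100.0 * total_loss_bu / reference_production_bu


def count_sign_shares(deltas: pd.DataFrame) -> tuple[float, float, float]:
    """Shares of producing counties with increased / improved / unchanged loss.

    Only counties with nonzero production are counted.  Returns
    ``(percent_increased, percent_improved, percent_unchanged)``; zero
    deltas form the third share and are excluded from the two headline
    shares.  The three shares sum to 100.
    """
    if len(deltas) == 0:
        raise ValueError("empty delta table")
    producing = deltas.loc[deltas["production_bu"] > 0, "delta_loss_bu"]
    n = len(producing)
    if n == 0:
        raise ValueError("no producing counties in delta table")
    n_up = int((producing > 0).sum())
    n_down = int((producing < 0).sum())
    n_zero = n - n_up - n_down
    return (100.0 * n_up / n, 100.0 * n_down / n, 100.0 * n_zero / n)


@dataclass
class ScenarioReport:
    """Domain-wide comparison of two scenario impact tables."""

    labels: tuple[str, str]
    deltas: pd.DataFrame
    regional: pd.DataFrame
    total_loss_bu: dict[str, float]
    total_loss_usd: dict[str, float]
    average_loss_bu: dict[str, float]
    reduction_percent: dict[str, float]
    difference_in_reduction_percent: float
    production_gain_bu: float
    production_gain_usd: float
    share_increased_percent: float
    share_improved_percent: float
    share_unchanged_percent: float
    reference_production_bu: float
    price_usd_per_bu: float

    def totals_frame(self) -> pd.DataFrame:
        """Tidy per-scenario totals plus the cross-scenario summary rows."""
        ref, pert = self.labels
        rows = [
            {"quantity": "total_loss_bu", ref: self.total_loss_bu[ref], pert: self.total_loss_bu[pert]},
            {"quantity": "average_loss_bu", ref: self.average_loss_bu[ref], pert: self.average_loss_bu[pert]},
            {"quantity": "total_loss_usd", ref: round(self.total_loss_usd[ref], 2), pert: round(self.total_loss_usd[pert], 2)},
            {"quantity": "reduction_percent", ref: self.reduction_percent[ref], pert: self.reduction_percent[pert]},
        ]
        df = pd.DataFrame(rows)
        extra = pd.DataFrame(
            [
                {"quantity": "difference_in_reduction_percent", ref: self.difference_in_reduction_percent, pert: np.nan},
                {"quantity": "production_gain_bu", ref: self.production_gain_bu, pert: np.nan},
                {"quantity": "production_gain_usd", ref: round(self.production_gain_usd, 2), pert: np.nan},
                {"quantity": "share_increased_percent", ref: self.share_increased_percent, pert: np.nan},
                {"quantity": "share_improved_percent", ref: self.share_improved_percent, pert: np.nan},
                {"quantity": "share_unchanged_percent", ref: self.share_unchanged_percent, pert: np.nan},
            ]
        )
        return pd.concat([df, extra], ignore_index=True)


def build_report(
    table_ref: pd.DataFrame,
    table_pert: pd.DataFrame,
    labels: tuple[str, str] = ("BAU", "C19"),
    price_usd_per_bu: float = DEFAULT_PRICE_USD_PER_BU,
    reference_production_bu: float | None = None,
) -> ScenarioReport:
    """Assemble the full two-scenario report.

    ``reference_production_bu`` is the denominator of the reduction
    percentage; by default it is the summed production of the counties
    in the tables (i.e. excluding any withheld records already dropped
    upstream).
    """
    ref, pert = labels
    deltas = scenario_difference(table_ref, table_pert)
    regional = regional_summary(deltas)

    # fsum: exact compensated summation, so the domain total equals the
    # sum of regional totals bit-for-bit regardless of grouping order
    totals_bu = {
        ref: math.fsum(table_ref["loss_bu"]),
        pert: math.fsum(table_pert["loss_bu"]),
    }
    averages = {
        ref: totals_bu[ref] / len(table_ref),
        pert: totals_bu[pert] / len(table_pert),
    }
    # bushels first, then price: the gain is exactly price x Bu-difference
    gain_bu = totals_bu[ref] - totals_bu[pert]
    gain_usd = gain_bu * price_usd_per_bu
    totals_usd = {k: v * price_usd_per_bu for k, v in totals_bu.items()}

    if reference_production_bu is None:
        reference_production_bu = float(table_ref["production_bu"].sum())
    red = {k: reduction_percent(v, reference_production_bu) for k, v in totals_bu.items()}
    up, down, unchanged = count_sign_shares(deltas)

    return ScenarioReport(
        labels=labels,
        deltas=deltas,
        regional=regional,
        total_loss_bu=totals_bu,
        total_loss_usd=totals_usd,
        average_loss_bu=averages,
        reduction_percent=red,
        difference_in_reduction_percent=red[ref] - red[pert],
        production_gain_bu=gain_bu,
        production_gain_usd=gain_usd,
        share_increased_percent=up,
        share_improved_percent=down,
        share_unchanged_percent=unchanged,
        reference_production_bu=float(reference_production_bu),
        price_usd_per_bu=float(price_usd_per_bu),
    )
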