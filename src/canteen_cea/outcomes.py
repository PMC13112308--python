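"""Order eligibility filtering and per-student dietary outcome computation.

An order enters the analysis only if it was placed through the mobile app
(and was therefore exposed to all choice-architecture strategies), for a
lunch break, on a usual canteen day, and contains a plausible number of items
(fifteen or fewer).  Excluded orders are tallied under a single reason each,
using the fixed precedence channel -> break -> day -> size.

Per student and period, the unit of economic analysis is the
:class:`StudentOutcome`: the mean energy (kJ) of the student's orders, the
proportions of items classified 'Everyday' / 'Occasional' / 'Should not be
sold' (items pooled across the student's orders, matching item-level odds),
and the shares of order energy derived from saturated fat (37 kJ/g) and
sugar (17 kJ/g).  Missing follow-up is handled by last observation carried
forward (LOCF): a student's baseline outcome is imputed as the follow-up
outcome, which conservatively estimates no change for that student.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "OrderRecord", "OrderItem", "StudentOutcome", "EXCLUSION_REASONS",
    "filter_eligible", "order_energy", "energy_shares",
    "student_period_summary", "locf_impute",
]

logger = logging.getLogger(__name__)

KJ_PER_G_SATFAT = 37.0
KJ_PER_G_SUGAR = 17.0
MAX_PLAUSIBLE_ITEMS = 15

#: exclusion precedence: an order excluded for several reasons is tallied
#: under the first applicable one
EXCLUSION_REASONS = ("channel", "break", "day", "size")

CLASSIFICATIONS = ("everyday", "occasional", "should_not_be_sold")


@dataclass(frozen=True)
class OrderItem:
    energy_kj: float
    satfat_g: float = 0.0
    sugar_g: float = 0.0
    sodium_mg: float = 0.0
    classification: str = "everyday"

    def __post_init__(self):
        for f in ("energy_kj", "satfat_g", "sugar_g", "sodium_mg"):
            v = getattr(self, f)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f} must be finite and >= 0, got {v}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class OrderRecord:
    """One lunch order (a set of items) for one student at one timepoint."""

    order_id: str
    student_id: str
    school_id: str
    arm: str
    period: str
    items: tuple
    channel: str = "app"
    break_type: str = "lunch"
    day_type: str = "usual"

    def __post_init__(self):
        if len(self.items) == 0:
            raise ValueError("an order must contain at least one item")


def order_energy(order: OrderRecord) -> float:
    """Total energy (kJ) of an order: sum of its items' energy."""
    return float(sum(i.energy_kj for i in order.items))


def energy_shares(order: OrderRecord) -> tuple[float, float]:
    """Shares of order energy from saturated fat and from sugar.

    share_satfat = 37 x total satfat (g) / total energy (kJ); share_sugar
    uses 17 kJ/g.  Undefined (raises) for a zero-energy order; callers flag
    such orders and exclude them from period means.
    """
    total = order_energy(order)
    if total <= 0:
        raise ValueError("energy shares undefined for a zero-energy order")
    satfat = sum(i.satfat_g for i in order.items)
    sugar = sum(i.sugar_g for i in order.items)
    return (KJ_PER_G_SATFAT * satfat / total, KJ_PER_G_SUGAR * sugar / total)


@dataclass(frozen=True)
class StudentOutcome:
    student_id: str
    school_id: str
    arm: str
    period: str
    n_orders: int
    mean_energy: float
    prop_everyday: float
    prop_occasional: float
    prop_should_not: float
    energy_share_satfat: float
    energy_share_sugar: float
    imputed: bool = False


# ---------------------------------------------------------------------------
# DataFrame pipeline (one row per item, order-level fields repeated)
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[OrderRecord]) -> pd.DataFrame:
    """Flatten :class:`OrderRecord` objects into the item-level table."""
    rows = []
    for r in records:
        for item in r.items:
            rows.append({
                "order_id": r.order_id, "student_id": r.student_id,
                "school_id": r.school_id, "arm": r.arm, "period": r.period,
                "channel": r.channel, "break_type": r.break_type,
                "day_type": r.day_type, "energy_kj": item.energy_kj,
                "satfat_g": item.satfat_g, "sugar_g": item.sugar_g,
                "sodium_mg": item.sodium_mg,
                "classification": item.classification,
            })
    return pd.DataFrame(rows)

def _exclusion_reason(orders: pd.DataFrame) -> pd.Series:
    """Per-order exclusion reason ('' = eligible), fixed precedence."""
    info = orders.groupby("order_id", sort=False).agg(
        n_items=("order_id", "size"), channel=("channel", "first"),
        break_type=("break_type", "first"), day_type=("day_type", "first"))
    reason = pd.Series("", index=info.index, dtype=object)
    reason[info["n_items"] > MAX_PLAUSIBLE_ITEMS] = "size"
    reason[info["day_type"] != "usual"] = "day"
    reason[info["break_type"] != "lunch"] = "break"
    reason[info["channel"] != "app"] = "channel"
    return reason


def filter_eligible(orders: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep analysable orders; tally one exclusion reason per dropped order.

    Eligible: app channel AND lunch break AND usual day AND <= 15 items.
    Returns the eligible item rows and a tally dict over
    :data:`EXCLUSION_REASONS` plus ``'eligible'``.
    """
    if orders.empty:
        return orders.copy(), {r: 0 for r in EXCLUSION_REASONS} | {"eligible": 0}
    reason = _exclusion_reason(orders)
    tally = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS}
    tally["eligible"] = int((reason == "").sum())
    keep = reason.loc[orders["order_id"]].to_numpy() == ""
    return orders.loc[keep].copy(), tally


def student_period_summary(orders: pd.DataFrame) -> pd.DataFrame:
    """Per-student, per-period outcomes from eligible item rows.

    For each (student, period): ``mean_energy`` is the mean over orders of the
    order's total energy; classification proportions pool items across all of
    the student's orders in the period; energy shares are averaged over orders
    with positive total energy.  Students with zero eligible orders in a
    period simply produce no row (handled later by LOCF).
    """
    if orders.empty:
        return pd.DataFrame(columns=[
            "student_id", "school_id", "arm", "period", "n_orders",
            "mean_energy", "prop_everyday", "prop_occasional",
            "prop_should_not", "energy_share_satfat", "energy_share_sugar",
            "imputed"])

    per_order = orders.groupby(
        ["student_id", "school_id", "arm", "period", "order_id"],
        observed=True, sort=False,
    ).agg(energy=("energy_kj", "sum"), satfat=("satfat_g", "sum"),
          sugar=("sugar_g", "sum")).reset_index()
    pos = per_order["energy"] > 0
    per_order.loc[pos, "share_satfat"] = (
        KJ_PER_G_SATFAT * per_order.loc[pos, "satfat"] / per_order.loc[pos, "energy"])
    per_order.loc[pos, "share_sugar"] = (
        KJ_PER_G_SUGAR * per_order.loc[pos, "sugar"] / per_order.loc[pos, "energy"])

    keys = ["student_id", "school_id", "arm", "period"]
    agg = per_order.groupby(keys, observed=True, sort=False).agg(
        n_orders=("order_id", "size"), mean_energy=("energy", "mean"),
        energy_share_satfat=("share_satfat", "mean"),
        energy_share_sugar=("share_sugar", "mean")).reset_index()

    cls = orders.assign(
        is_e=orders["classification"] == "everyday",
        is_o=orders["classification"] == "occasional",
        is_s=orders["classification"] == "should_not_be_sold",
    ).groupby(keys, observed=True, sort=False)[["is_e", "is_o", "is_s"]].mean()
    cls.columns = ["prop_everyday", "prop_occasional", "prop_should_not"]

    out = agg.merge(cls.reset_index(), on=keys)
    out["imputed"] = False
    return out.sort_values(["student_id", "period"]).reset_index(drop=True)


def locf_impute(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Complete the follow-up period by carrying baseline values forward.

    Students with a baseline record but no follow-up record receive a copy of
    their baseline outcome as the follow-up value, flagged ``imputed``.
    Students with follow-up but no baseline cannot be carried forward and are
    excluded entirely, with a logged warning.  Returns both periods, with the
    follow-up period complete over the baseline cohort.
    """
    base = outcomes[outcomes["period"] == "baseline"]
    fup = outcomes[outcomes["period"] == "followup"]

    orphans = set(fup["student_id"]) - set(base["student_id"])
    if orphans:
        logger.warning(
            "%d student(s) have follow-up but no baseline outcomes and are "
            "excluded from analysis: %s", len(orphans),
            sorted(orphans)[:10])
        fup = fup[~fup["student_id"].isin(orphans)]

    missing = base[~base["student_id"].isin(fup["student_id"])]
    imputed = missing.assign(period="followup", imputed=True)
    completed = pd.concat([base, fup, imputed], ignore_index=True)
    return completed.sort_values(["student_id", "period"]).reset_index(drop=True)
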