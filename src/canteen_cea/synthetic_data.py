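"""Synthetic cluster-trial generator for online canteen purchasing data.

The real trial's student-level purchasing data are held by the online canteen
provider and are not publicly deposited.  This module generates datasets with
the statistical structure the economic analysis assumes — a two-arm cluster
trial (schools randomised, students nested in schools), two 8-week observation
periods, item-level lunch orders with nutrient content and menu classification,
and an activity-based cost ledger for the intervention arm — so that every
downstream stage (costing, outcomes, CEA, sensitivity) is testable end to end.

Design of the generating process
--------------------------------
* Order energy is drawn per order from a zero-truncated normal around a
  student-level mean; item energies are a random (flat Dirichlet) split of the
  order total.  The analysis consumes order totals, so item physics are not
  modelled mechanistically.
* The intervention effect is a location shift of ``energy_effect`` kJ applied
  to intervention-arm follow-up orders, matching an additive between-group
  difference on order energy.
* Each item is independently labelled 'Everyday' with probability
  ``everyday_baseline_prob``, shifted on the odds scale by
  ``everyday_odds_ratio`` for intervention-arm follow-up items.  The remainder
  is split 'Occasional' / 'Should not be sold' at a fixed configurable ratio.
* Dropout at follow-up is completely at random at rate
  ``1 - followup_retention``; dropped students place no follow-up orders.
* A configurable fraction of orders is made ineligible for analysis (web
  channel, non-lunch break, special day, or an implausible >15-item order),
  with the mechanism chosen uniformly, so that every filter branch downstream
  is exercised.
* Per-school intervention delivery costs scale with a school-level factor
  drawn uniformly from ``[1 - cost_spread, 1 + cost_spread]``; bearer means
  therefore match ``cost_mean_health`` and ``cost_mean_school`` in
  expectation.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``TrialConfig.seed``; a fixed config + seed reproduces the dataset
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

__all__ = ["TrialConfig", "SyntheticTrial", "generate_trial", "generate_cost_ledger"]

CATEGORIES = ("collect_menu", "assess_menu", "execute_strategies")
BEARERS = ("health_service", "school")

#: Split of the per-school bearer mean across activity categories.  Only the
#: bearer totals and the execute-strategies health-service component are
#: anchored to published figures; the remaining split is a calibration choice.
_HEALTH_SPLIT = {"collect_menu": 250.0 / 518.0, "assess_menu": 156.0 / 518.0,
                 "execute_strategies": 112.0 / 518.0}
_SCHOOL_SPLIT = {"collect_menu": 0.60, "assess_menu": 0.10,
                 "execute_strategies": 0.30}
#: 2018 award-style hourly rates: health-service project officer and canteen
#: manager (fast-food award level), both with a 25 % oncost loading.
_HOURLY_RATE = {"health_service": 60.00, "school": 21.60}
_ONCOST = 1.25

ORDER_COLUMNS = [
    "order_id", "student_id", "school_id", "arm", "period", "channel",
    "break_type", "day_type", "energy_kj", "satfat_g", "sugar_g",
    "sodium_mg", "classification",
]


class TrialConfig(BaseModel):
    """Parameters of the synthetic cluster trial.

    Defaults emulate the published trial structure: 9 intervention + 8 control
    schools, ~2200 students with at least one baseline order, 82 % follow-up
    retention, a 69 kJ mean energy reduction, an odds ratio of 1.7 on
    'Everyday' purchasing, and per-school delivery costs averaging $518
    (health service) + $50 (school) in 2018 AUD.

    Values not anchored to a published figure (order-energy mean/SD, order and
    item count distributions, nutrient shares, the category split of costs)
    are calibration choices documented in ``docs/methods.md``.
    """

    model_config = {"extra": "forbid"}

    n_intervention_schools: int = Field(9, ge=1)
    n_control_schools: int = Field(8, ge=1)

    # Negative-binomial (mean, dispersion) school sizes; clipped at >=1.
    students_per_school_mean: float = Field(130.0, gt=0)
    students_per_school_dispersion: float = Field(12.0, gt=0)

    # Orders per student per 8-week period; >=1 at baseline by construction
    # (the sampling frame is students with at least one baseline order).
    orders_per_student_mean: float = Field(4.0, gt=0)
    orders_per_student_dispersion: float = Field(3.0, gt=0)

    baseline_order_energy_mean: float = Field(1400.0, gt=0)  # kJ
    baseline_order_energy_sd: float = Field(450.0, gt=0)  # kJ, total SD
    #: share of the energy SD that is between students (shared student mean)
    energy_between_student_frac: float = Field(0.4, ge=0, le=1)

    #: mean follow-up reduction in intervention-arm order energy, kJ
    energy_effect: float = 69.0
    #: chosen so that the default odds ratio of 1.7 implies a +9.8 pp shift
    everyday_baseline_prob: float = Field(0.70, ge=0, le=1)
    everyday_odds_ratio: float = Field(1.7, gt=0)
    #: of items not labelled Everyday, the fraction labelled Occasional
    occasional_share_of_rest: float = Field(0.75, ge=0, le=1)

    followup_retention: float = Field(0.82, ge=0, le=1)

    items_per_order_mean: float = Field(2.5, ge=1)  # support 1..15 when eligible
    ineligible_order_rate: float = Field(0.05, ge=0, le=1)

    cost_mean_health: float = Field(518.0, ge=0)  # AUD per school
    cost_mean_school: float = Field(50.0, ge=0)  # AUD per school
    #: per-school cost factor ~ Uniform(1-cost_spread, 1+cost_spread)
    cost_spread: float = Field(0.45, ge=0, lt=1)

    #: schools where all strategies were delivered in full (per-protocol set)
    n_per_protocol_schools: int = Field(5, ge=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check_cross_field(self) -> "TrialConfig":
        if self.n_per_protocol_schools > self.n_intervention_schools:
            raise ValueError(
                "n_per_protocol_schools cannot exceed n_intervention_schools"
            )
        return self


@dataclass
class SyntheticTrial:
    """A generated trial: item-level orders, cost ledger, and ground truth.

    ``orders`` has one row per purchased item (order-level fields repeated),
    ``cost_ledger`` one row per costed activity, and ``truth`` records the
    generating parameters actually used plus derived facts (arm sizes,
    per-protocol school set) that tests and analyses may condition on.
    """

    orders: pd.DataFrame
    cost_ledger: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float,
                  size: int) -> np.ndarray:
    """NB draws parameterised by (mean, dispersion k); var = m + m^2/k."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _or_shift(p: float, odds_ratio: float) -> float:
    """Shift probability ``p`` by ``odds_ratio`` on the odds scale."""
    if p in (0.0, 1.0):
        return p
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


def generate_trial(config: TrialConfig) -> SyntheticTrial:
    """Generate a complete synthetic trial dataset from ``config``.

    Returns orders for both arms and both periods plus the intervention-arm
    cost ledger.  A fraction ``1 - followup_retention`` of students, chosen
    completely at random, place no follow-up orders.
    """
    rng = np.random.default_rng(config.seed)

    schools = (
        [f"I{i + 1:02d}" for i in range(config.n_intervention_schools)]
        + [f"C{i + 1:02d}" for i in range(config.n_control_schools)]
    )
    arms = (["intervention"] * config.n_intervention_schools
            + ["control"] * config.n_control_schools)

    sizes = np.maximum(
        1,
        _neg_binomial(rng, config.students_per_school_mean,
                      config.students_per_school_dispersion, len(schools)),
    )

    # --- student table -----------------------------------------------------
    student_school = np.repeat(np.arange(len(schools)), sizes)
    n_students = int(sizes.sum())
    student_ids = np.array(
        [f"{schools[s]}-S{i:04d}"
         for s, i in zip(student_school, _within_counter(student_school))]
    )
    between_sd = config.energy_between_student_frac * config.baseline_order_energy_sd
    within_sd = float(np.sqrt(max(config.baseline_order_energy_sd**2
                                  - between_sd**2, 1e-12)))
    student_mu = rng.normal(config.baseline_order_energy_mean, between_sd,
                            n_students)
    retained = rng.random(n_students) < config.followup_retention

    # --- order counts ------------------------------------------------------
    n_orders_base = np.maximum(
        1, _neg_binomial(rng, config.orders_per_student_mean,
                         config.orders_per_student_dispersion, n_students))
    n_orders_fup = np.where(
        retained,
        np.maximum(1, _neg_binomial(rng, config.orders_per_student_mean,
                                    config.orders_per_student_dispersion,
                                    n_students)),
        0,
    )

    frames = []
    next_order = 0
    for period, counts in (("baseline", n_orders_base),
                           ("followup", n_orders_fup)):
        stu_idx = np.repeat(np.arange(n_students), counts)
        n_orders = len(stu_idx)
        if n_orders == 0:
            continue
        order_ids = np.arange(next_order, next_order + n_orders)
        next_order += n_orders

        arm = np.array(arms, dtype=object)[student_school[stu_idx]]
        mu = student_mu[stu_idx].copy()
        if period == "followup":
            mu[arm == "intervention"] -= config.energy_effect

        # zero-truncated normal order totals
        a = (0.0 - mu) / within_sd
        order_energy = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=within_sd,
                                           random_state=rng)

        # item counts: 1 + Poisson, capped at the 15-item plausibility limit
        n_items = np.minimum(
            1 + rng.poisson(config.items_per_order_mean - 1.0, n_orders), 15)

        channel = np.full(n_orders, "app", dtype=object)
        break_type = np.full(n_orders, "lunch", dtype=object)
        day_type = np.full(n_orders, "usual", dtype=object)
        bad = rng.random(n_orders) < config.ineligible_order_rate
        kind = rng.integers(0, 4, n_orders)
        channel[bad & (kind == 0)] = "web"
        break_type[bad & (kind == 1)] = "other"
        day_type[bad & (kind == 2)] = "special"
        oversize = bad & (kind == 3)
        n_items[oversize] = rng.integers(16, 21, int(oversize.sum()))

        # Everyday probability per order context
        p_eday = np.full(n_orders, config.everyday_baseline_prob)
        if period == "followup":
            p_eday[arm == "intervention"] = _or_shift(
                config.everyday_baseline_prob, config.everyday_odds_ratio)

        frames.append(_expand_items(
            rng, config, order_ids, student_ids[stu_idx],
            np.array(schools, dtype=object)[student_school[stu_idx]], arm,
            period, channel, break_type, day_type, order_energy, n_items,
            p_eday))

    orders = pd.concat(frames, ignore_index=True)[ORDER_COLUMNS]

    intervention_schools = [s for s, a in zip(schools, arms)
                            if a == "intervention"]
    ledger = generate_cost_ledger(config, intervention_schools, rng=rng)
    per_protocol = sorted(rng.choice(intervention_schools,
                                     size=config.n_per_protocol_schools,
                                     replace=False).tolist())

    truth = {
        "config": config.model_dump(),
        "schools": dict(zip(schools, map(int, sizes))),
        "arms": dict(zip(schools, arms)),
        "n_students": n_students,
        "n_students_intervention": int(sizes[: config.n_intervention_schools].sum()),
        "n_students_control": int(sizes[config.n_intervention_schools:].sum()),
        "per_protocol_schools": per_protocol,
        "everyday_prob_shifted": _or_shift(config.everyday_baseline_prob,
                                           config.everyday_odds_ratio),
    }
    return SyntheticTrial(orders=orders, cost_ledger=ledger, truth=truth)


def _within_counter(group_idx: np.ndarray) -> np.ndarray:
    """Running count within consecutive groups (0-based)."""
    out = np.zeros(len(group_idx), dtype=int)
    if len(group_idx) == 0:
        return out
    boundaries = np.flatnonzero(np.diff(group_idx)) + 1
    starts = np.concatenate(([0], boundaries))
    for s, e in zip(starts, np.append(boundaries, len(group_idx))):
        out[s:e] = np.arange(e - s)
    return out


def _expand_items(rng, config, order_ids, student_ids, school_ids, arm, period,
                  channel, break_type, day_type, order_energy, n_items,
                  p_eday) -> pd.DataFrame:
    """Expand order-level draws into one row per item."""
    item_order = np.repeat(np.arange(len(order_ids)), n_items)
    total_items = len(item_order)

    # flat-Dirichlet split of the order total across its items
    g = rng.exponential(1.0, total_items)
    offsets = np.concatenate(([0], np.cumsum(n_items)[:-1]))
    gsum = np.add.reduceat(g, offsets)
    energy = order_energy[item_order] * g / gsum[item_order]

    u = rng.random(total_items)
    everyday = u < p_eday[item_order]
    occ = rng.random(total_items) < config.occasional_share_of_rest
    classification = np.where(
        everyday, "everyday", np.where(occ, "occasional", "should_not_be_sold"))

    satfat = rng.uniform(0.08, 0.18, total_items) * energy / 37.0
    sugar = rng.uniform(0.12, 0.28, total_items) * energy / 17.0
    sodium = rng.uniform(0.6, 1.2, total_items) * energy

    return pd.DataFrame({
        "order_id": order_ids[item_order],
        "student_id": student_ids[item_order],
        "school_id": school_ids[item_order],
        "arm": arm[item_order],
        "period": period,
        "channel": channel[item_order],
        "break_type": break_type[item_order],
        "day_type": day_type[item_order],
        "energy_kj": np.round(energy, 1),
        "satfat_g": np.round(satfat, 2),
        "sugar_g": np.round(sugar, 2),
        "sodium_mg": np.round(sodium, 1),
        "classification": classification,
    })


def generate_cost_ledger(
    config: TrialConfig,
    school_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw an activity-based cost ledger for the intervention schools.

    Each school receives one entry per category x bearer; minutes are set so
    that entry cost = minutes/60 x rate x oncost hits the school's share of
    the configured bearer mean, scaled by a school-level factor drawn from
    ``Uniform(1 - cost_spread, 1 + cost_spread)``.  An empty ``school_ids``
    yields an empty ledger.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    factors = rng.uniform(1.0 - config.cost_spread, 1.0 + config.cost_spread,
                          len(school_ids))
    bearer_mean = {"health_service": config.cost_mean_health,
                   "school": config.cost_mean_school}
    split = {"health_service": _HEALTH_SPLIT, "school": _SCHOOL_SPLIT}
    desc = {
        ("collect_menu", "health_service"): "project officer collates menu items and schedules canteen calls",
        ("collect_menu", "school"): "canteen manager supplies menu and product details",
        ("assess_menu", "health_service"): "dietitian classifies menu against canteen strategy",
        ("assess_menu", "school"): "canteen manager clarifies recipes for assessment",
        ("execute_strategies", "health_service"): "project officer switches on online menu strategies",
        ("execute_strategies", "school"): "canteen manager reviews modified online menu",
    }

    rows = []
    for school, f in zip(school_ids, factors):
        for bearer in BEARERS:
            rate = _HOURLY_RATE[bearer]
            for cat in CATEGORIES:
                target = bearer_mean[bearer] * split[bearer][cat] * f
                minutes = round(60.0 * target / (rate * _ONCOST), 2)
                rows.append({
                    "school_id": school, "category": cat, "bearer": bearer,
                    "minutes": minutes, "hourly_rate": rate,
                    "oncost_multiplier": _ONCOST,
                    "description": desc[(cat, bearer)],
                })
    return pd.DataFrame(
        rows, columns=["school_id", "category", "bearer", "minutes",
                       "hourly_rate", "oncost_multiplier", "description"])
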