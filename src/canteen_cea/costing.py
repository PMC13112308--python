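"""Activity-based (micro-)costing of intervention delivery.

Each costed activity is valued as ``minutes/60 x hourly_rate x oncost``
rounded half-up to the cent; aggregation thereafter is exact integer-cent
arithmetic, so category and bearer partitions reconcile to the school total
to the cent.  Two analytic perspectives are supported: ``health_service``
(health-service bearer only) and ``societal`` (health service plus school
opportunity costs).  Usual-practice costs displaced by the intervention are
taken to be zero, and no discounting is applied over the 16-month horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, Field

from .synthetic_data import BEARERS, CATEGORIES

__all__ = [
    "CostEntry", "CostSummary", "value_entry", "value_entry_cents",
    "summarise_costs", "per_student_costs", "PERSPECTIVES",
]

PERSPECTIVES = ("health_service", "societal")


class CostEntry(BaseModel):
    """One costed activity: staff time valued at an oncost-loaded wage."""

    model_config = {"extra": "forbid"}

    school_id: str
    category: str
    bearer: str
    minutes: float = Field(ge=0, allow_inf_nan=False)
    hourly_rate: float = Field(gt=0, allow_inf_nan=False)
    oncost_multiplier: float = Field(1.0, ge=1, allow_inf_nan=False)
    description: str = ""

    @classmethod
    def _check_labels(cls, category: str, bearer: str) -> None:
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {CATEGORIES}")
        if bearer not in BEARERS:
            raise ValueError(
                f"unknown bearer {bearer!r}; expected one of {BEARERS}")

    def model_post_init(self, __context) -> None:
        self._check_labels(self.category, self.bearer)


def value_entry_cents(minutes: float, hourly_rate: float,
                      oncost_multiplier: float = 1.0) -> int:
    """Value of an activity in integer cents, rounded half-up."""
    if minutes < 0 or hourly_rate < 0:
        raise ValueError("minutes and hourly_rate must be non-negative")
    amount = (Decimal(str(minutes)) / Decimal(60)
              * Decimal(str(hourly_rate)) * Decimal(str(oncost_multiplier)))
    return int(amount.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
               * 100)


def value_entry(entry: CostEntry) -> float:
    """AUD value of one ledger entry: minutes/60 x rate x oncost, to the cent."""
    return value_entry_cents(entry.minutes, entry.hourly_rate,
                             entry.oncost_multiplier) / 100.0


@dataclass
class CostSummary:
    """Per-school cost aggregation under one perspective.

    All monetary fields are AUD floats derived from exact integer-cent sums;
    ``per_school`` maps school -> {'by_category', 'by_bearer', 'total'} and
    both partitions sum to the school total to the cent.
    """

    perspective: str
    per_school: dict
    overall_total: float
    mean_per_school: float
    min_per_school: float
    max_per_school: float

    @property
    def school_totals(self) -> dict:
        return {s: d["total"] for s, d in self.per_school.items()}


def _ledger_frame(entries) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of CostEntry."""
    if isinstance(entries, pd.DataFrame):
        df = entries.copy()
    else:
        df = pd.DataFrame([e.model_dump() for e in entries])
    if df.empty:
        raise ValueError("cost ledger is empty")
    bad_cat = set(df["category"]) - set(CATEGORIES)
    bad_bearer = set(df["bearer"]) - set(BEARERS)
    if bad_cat:
        raise ValueError(f"unknown categories in ledger: {sorted(bad_cat)}")
    if bad_bearer:
        raise ValueError(f"unknown bearers in ledger: {sorted(bad_bearer)}")
    if (df["minutes"] < 0).any() or (df["hourly_rate"] < 0).any():
        raise ValueError("negative minutes or hourly_rate in ledger")
    return df


def summarise_costs(entries, perspective: str = "societal") -> CostSummary:
    """Aggregate a cost ledger by school, category and bearer.

    ``health_service`` keeps only health-service-borne entries; ``societal``
    keeps both bearers.  Categories with no entries for a school are reported
    as $0, not omitted.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(
            f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")
    df = _ledger_frame(entries)
    if perspective == "health_service":
        df = df[df["bearer"] == "health_service"]

    schools = sorted(_ledger_frame(entries)["school_id"].unique())
    cents = df.apply(
        lambda r: value_entry_cents(r["minutes"], r["hourly_rate"],
                                    r["oncost_multiplier"]), axis=1,
    ) if not df.empty else pd.Series(dtype=int)
    df = df.assign(cents=cents)

    per_school: dict = {}
    totals = []
    for school in schools:
        sub = df[df["school_id"] == school]
        by_cat = {c: int(sub.loc[sub["category"] == c, "cents"].sum())
                  for c in CATEGORIES}
        by_bearer = {b: int(sub.loc[sub["bearer"] == b, "cents"].sum())
                     for b in BEARERS}
        total = int(sub["cents"].sum())
        assert sum(by_cat.values()) == total == sum(by_bearer.values())
        per_school[school] = {
            "by_category": {c: v / 100.0 for c, v in by_cat.items()},
            "by_bearer": {b: v / 100.0 for b, v in by_bearer.items()},
            "total": total / 100.0,
        }
        totals.append(total)

    overall = sum(totals)
    return CostSummary(
        perspective=perspective,
        per_school=per_school,
        overall_total=overall / 100.0,
        mean_per_school=overall / len(totals) / 100.0,
        min_per_school=min(totals) / 100.0,
        max_per_school=max(totals) / 100.0,
    )


def per_student_costs(
    summary: CostSummary,
    students_per_school: Mapping[str, int],
    pooling: str = "pooled",
) -> dict:
    """Cost per student for the costed (intervention) arm.

    ``pooled`` divides the arm's total cost by the arm's total student count —
    the convention used for arm-level incremental costs.  ``per_school``
    divides each school's cost by its own students and averages across
    schools weighting by students; algebraically this coincides with the
    pooled value (sum_s (c_s/n_s) n_s / sum_s n_s = sum c / sum n), so both
    modes report the same mean alongside the per-school detail.

    Returns ``{"per_school": {school: AUD}, "mean": AUD, "pooling": mode}``.
    Control schools (cost 0) may be absent from the map; costed schools must
    have a count >= 1.
    """
    if pooling not in ("pooled", "per_school"):
        raise ValueError("pooling must be 'pooled' or 'per_school'")
    per_school = {}
    for school, detail in summary.per_school.items():
        if school not in students_per_school:
            raise ValueError(f"no student count for costed school {school!r}")
        n = students_per_school[school]
        if n < 1:
            raise ValueError(f"school {school!r} has zero students; "
                             "per-student cost undefined")
        per_school[school] = detail["total"] / n

    n_total = sum(students_per_school[s] for s in summary.per_school)
    if pooling == "pooled":
        mean = summary.overall_total / n_total
    else:
        mean = sum(per_school[s] * students_per_school[s]
                   for s in summary.per_school) / n_total
    return {"per_school": per_school, "mean": mean, "pooling": pooling}
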