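"""One-way sensitivity scenarios over the cost-effectiveness analysis.

Each scenario is a declarative modification of the baseline inputs — wage
substitution (e.g. higher canteen-manager rates), removal of a cost
component (e.g. the detailed menu assessment, for settings where a simpler
free menu-checking service suffices), or restriction to a school subset
(per-protocol: the intervention schools where every strategy was delivered
and maintained).  Scenarios are applied to deep copies, never mutating the
baseline, and every scenario is analysed with a common seed so that
differences between scenario results reflect the scenario change alone, not
bootstrap noise.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cea import AnalysisInputs, CEAResult, CEASettings, run_cea
from .synthetic_data import BEARERS, CATEGORIES

__all__ = ["ScenarioSpec", "apply_scenario", "run_scenarios"]


class ScenarioSpec(BaseModel):
    """One sensitivity scenario: at least one modification of the baseline.

    ``wage_overrides`` maps a bearer (``health_service`` / ``school``) to a
    replacement hourly rate; ``drop_categories`` removes cost categories
    (never all three); ``school_subset`` restricts the intervention arm to a
    list of school ids or to the ``"per_protocol"`` set; ``effect_override``
    substitutes an externally estimated incremental effect for subset
    analyses whose published effect came from a different estimator.
    """

    model_config = {"extra": "forbid"}

    name: str
    wage_overrides: dict[str, float] = Field(default_factory=dict)
    drop_categories: list[str] = Field(default_factory=list)
    school_subset: Optional[Union[list[str], str]] = None
    effect_override: Optional[float] = None

    @model_validator(mode="after")
    def _validate(self) -> "ScenarioSpec":
        if (not self.wage_overrides and not self.drop_categories
                and self.school_subset is None
                and self.effect_override is None):
            raise ValueError(f"scenario {self.name!r} modifies nothing")
        unknown = set(self.drop_categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown cost categories {sorted(unknown)}")
        if set(self.drop_categories) >= set(CATEGORIES):
            raise ValueError("cannot drop all three cost categories")
        bad_bearers = set(self.wage_overrides) - set(BEARERS)
        if bad_bearers:
            raise ValueError(
                f"wage_overrides keys must be bearers {BEARERS}, "
                f"got {sorted(bad_bearers)}")
        for bearer, rate in self.wage_overrides.items():
            if rate <= 0:
                raise ValueError(f"override rate for {bearer!r} must be > 0")
        if isinstance(self.school_subset, str) \
                and self.school_subset != "per_protocol":
            raise ValueError(
                "school_subset must be a list of ids or 'per_protocol'")
        return self


def apply_scenario(inputs: AnalysisInputs,
                   spec: ScenarioSpec) -> tuple[AnalysisInputs, list[str]]:
    """Return a deep-modified copy of the inputs plus a modification log.

    The original inputs are untouched.  Unknown school ids in a subset raise.
    """
    ledger = inputs.cost_ledger.copy(deep=True)
    orders = inputs.orders.copy(deep=True)
    log: list[str] = []

    for bearer, rate in spec.wage_overrides.items():
        n = int((ledger["bearer"] == bearer).sum())
        ledger.loc[ledger["bearer"] == bearer, "hourly_rate"] = rate
        log.append(f"hourly_rate for bearer {bearer!r} set to "
                   f"{rate:.2f} on {n} entries")

    if spec.drop_categories:
        before = len(ledger)
        ledger = ledger[~ledger["category"].isin(spec.drop_categories)]
        log.append(f"dropped categories {sorted(spec.drop_categories)} "
                   f"({before - len(ledger)} entries removed)")

    if spec.school_subset is not None:
        if spec.school_subset == "per_protocol":
            if not inputs.per_protocol_schools:
                raise ValueError(
                    "per_protocol subset requested but the inputs carry no "
                    "per-protocol school list")
            subset = list(inputs.per_protocol_schools)
        else:
            subset = list(spec.school_subset)
        known = set(orders.loc[orders["arm"] == "intervention", "school_id"])
        known |= set(ledger["school_id"])
        unknown = set(subset) - known
        if unknown:
            raise ValueError(
                f"school subset contains unknown ids: {sorted(unknown)}")
        ledger = ledger[ledger["school_id"].isin(subset)]
        keep = (orders["arm"] == "control") | orders["school_id"].isin(subset)
        orders = orders[keep]
        log.append(f"intervention arm restricted to {len(subset)} schools: "
                   f"{sorted(subset)}")

    if spec.effect_override is not None:
        log.append(f"incremental effect overridden to {spec.effect_override}")

    modified = AnalysisInputs(
        orders=orders.reset_index(drop=True),
        cost_ledger=ledger.reset_index(drop=True),
        per_protocol_schools=list(inputs.per_protocol_schools or []),
    )
    return modified, log


def run_scenarios(
    inputs: AnalysisInputs,
    specs: Sequence[ScenarioSpec],
    settings: CEASettings,
) -> tuple[pd.DataFrame, dict]:
    """Run the baseline plus every scenario with common random numbers.

    Returns a comparison table (one row per scenario with point estimates,
    intervals and the ICER delta versus baseline) and the full
    :class:`CEAResult` per scenario.  A failure inside any scenario aborts
    with the scenario name attached.
    """
    if not specs:
        raise ValueError("no scenarios supplied")

    results: dict[str, CEAResult] = {
        "baseline": run_cea(inputs, settings)}
    logs: dict[str, list[str]] = {"baseline": []}
    for spec in specs:
        try:
            modified, log = apply_scenario(inputs, spec)
            results[spec.name] = run_cea(modified, settings,
                                         effect_override=spec.effect_override)
            logs[spec.name] = log
        except Exception as exc:
            raise RuntimeError(f"scenario {spec.name!r} failed: {exc}") from exc

    base_icer = results["baseline"].icer.value
    rows = []
    for name, res in results.items():
        icer_val = res.icer.value
        rows.append({
            "scenario": name,
            "delta_cost": res.delta_cost,
            "delta_effect": res.delta_effect,
            "icer": icer_val,
            "icer_label": res.icer.label,
            "ui_icer_lower": res.ui_icer.get("lower"),
            "ui_icer_upper": res.ui_icer.get("upper"),
            "icer_delta_vs_baseline": (
                icer_val - base_icer
                if icer_val is not None and base_icer is not None else None),
            "modifications": "; ".join(logs[name]),
        })
    return pd.DataFrame(rows), results
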