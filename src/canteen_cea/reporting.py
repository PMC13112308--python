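"""Orchestration, file schemas and rendering of result artefacts.

A *run bundle* is the complete output of one analysis: the (synthetic) order
table and cost ledger, the exclusion tally, per-student outcomes, cost
summaries under both perspectives, one CEA result per outcome x perspective,
the sensitivity-scenario comparison table, and a manifest tying every file to
the configuration hash and seed.  Re-running with the same configuration and
seed reproduces byte-identical CSV/JSON outputs (the manifest's timestamp is
the only non-deterministic field, and it is confined to the manifest).

Monetary values are stored at full precision; rendered tables display two
decimals.  Plot-ready data (cost-effectiveness plane replicates, CEAC) are
always emitted as CSV; image rendering is left to the caller.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import (AnalysisInputs, CEAResult, CEASettings, EffectSpec, run_cea)
from .costing import PERSPECTIVES, summarise_costs, value_entry_cents
from .outcomes import filter_eligible, locf_impute, student_period_summary
from .sensitivity import ScenarioSpec, run_scenarios
from .synthetic_data import (BEARERS, CATEGORIES, ORDER_COLUMNS, TrialConfig,
                             generate_trial)

__all__ = [
    "RunManifest", "run_pipeline", "render_tables", "default_scenarios",
    "write_orders_csv", "read_orders_csv", "write_ledger_csv",
    "read_ledger_csv", "load_config",
]

_ORDER_DTYPES = {
    "order_id": "int64", "student_id": "string", "school_id": "string",
    "arm": "string", "period": "string", "channel": "string",
    "break_type": "string", "day_type": "string", "energy_kj": "float64",
    "satfat_g": "float64", "sugar_g": "float64", "sodium_mg": "float64",
    "classification": "string",
}
_LEDGER_DTYPES = {
    "school_id": "string", "category": "string", "bearer": "string",
    "minutes": "float64", "hourly_rate": "float64",
    "oncost_multiplier": "float64", "description": "string",
}


def write_orders_csv(orders: pd.DataFrame, path) -> None:
    orders[ORDER_COLUMNS].to_csv(path, index=False)


def read_orders_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=_ORDER_DTYPES)
    for col, dt in _ORDER_DTYPES.items():
        if dt == "string":
            df[col] = df[col].astype(object)
    return df


def write_ledger_csv(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False)


def read_ledger_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=_LEDGER_DTYPES)
    for col, dt in _LEDGER_DTYPES.items():
        if dt == "string":
            df[col] = df[col].astype(object)
    return df


def load_config(path) -> dict:
    """Read a structured YAML config: trial, cea and scenario sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {
        "trial": TrialConfig(**raw.get("trial", {})),
        "cea": raw.get("cea", {}),
        "scenarios": [ScenarioSpec(**s) for s in raw.get("scenarios", [])],
    }
    return out


@dataclass
class RunManifest:
    """Provenance of one run: config hash, seeds, versions, file checksums."""

    manifest_id: str
    config_hash: str
    seed: int
    package_version: str
    created_at: str
    files: dict = field(default_factory=dict)

    @classmethod
    def create(cls, config: TrialConfig, seed: int) -> "RunManifest":
        config_hash = hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest()
        return cls(
            manifest_id=f"{config_hash[:12]}-{seed}",
            config_hash=config_hash,
            seed=seed,
            package_version=__version__,
            created_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def register(self, path: Path) -> None:
        self.files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def default_scenarios(school_wage: float = 21.60) -> list[ScenarioSpec]:
    """The standard one-way scenario set.

    Wage substitution for canteen managers (a 1.5x award rate), removal of
    the detailed menu-assessment component (the setting where a free
    menu-checking service already classifies the menu), and the per-protocol
    school subset.
    """
    return [
        ScenarioSpec(name="higher_canteen_wages",
                     wage_overrides={"school": round(school_wage * 1.5, 2)}),
        ScenarioSpec(name="no_menu_assessment",
                     drop_categories=["assess_menu"]),
        ScenarioSpec(name="per_protocol", school_subset="per_protocol"),
    ]


def run_pipeline(
    config: TrialConfig,
    seed: int | None = None,
    out_dir=None,
    B: int = 2000,
    unit: str = "student",
    estimator: str = "diff_in_diff",
    scenarios: list[ScenarioSpec] | None = None,
) -> dict:
    """Simulate (or accept) a trial and run the full economic evaluation.

    Produces cost summaries, per-student outcomes, CEA results for both
    outcomes under both perspectives, the scenario comparison, and — when
    ``out_dir`` is given — writes every artefact plus a manifest.  All
    computation happens before any file is written, so a failing stage never
    leaves a partial bundle.
    """
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    manifest = RunManifest.create(config, config.seed)

    trial = generate_trial(config)
    inputs = AnalysisInputs(
        orders=trial.orders, cost_ledger=trial.cost_ledger,
        per_protocol_schools=trial.truth["per_protocol_schools"])

    eligible, tally = filter_eligible(trial.orders)
    outcomes = student_period_summary(eligible)
    completed = locf_impute(outcomes)
    cost_summaries = {p: summarise_costs(trial.cost_ledger, p)
                      for p in PERSPECTIVES}

    cea_results: dict[str, CEAResult] = {}
    for outcome in ("energy_reduction_kj", "everyday_pp_increase"):
        for perspective in PERSPECTIVES:
            settings = CEASettings(
                spec=EffectSpec(outcome=outcome, estimator=estimator),
                perspective=perspective, B=B, unit=unit, seed=config.seed)
            cea_results[f"{outcome}__{perspective}"] = run_cea(inputs,
                                                               settings)

    scenario_settings = CEASettings(
        spec=EffectSpec(outcome="energy_reduction_kj", estimator=estimator),
        perspective="health_service", B=B, unit=unit, seed=config.seed)
    scenario_table, scenario_results = run_scenarios(
        inputs, scenarios or default_scenarios(), scenario_settings)

    cost_table, icer_table = render_tables(trial.cost_ledger, cea_results)

    bundle = {
        "config": config, "manifest": manifest, "trial": trial,
        "exclusion_tally": tally, "outcomes": completed,
        "cost_summaries": cost_summaries, "cea_results": cea_results,
        "scenario_table": scenario_table,
        "scenario_results": scenario_results,
        "cost_table": cost_table, "icer_table": icer_table,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: RunManifest = bundle["manifest"]

    paths = []

    def _csv(df: pd.DataFrame, name: str):
        p = out_dir / name
        df.to_csv(p, index=False)
        paths.append(p)

    def _json(payload, name: str):
        p = out_dir / name
        payload = {"manifest_id": manifest.manifest_id, **payload}
        p.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                default=_json_default) + "\n")
        paths.append(p)

    write_orders_csv(bundle["trial"].orders, out_dir / "orders.csv")
    paths.append(out_dir / "orders.csv")
    write_ledger_csv(bundle["trial"].cost_ledger, out_dir / "cost_ledger.csv")
    paths.append(out_dir / "cost_ledger.csv")

    _json({"tally": bundle["exclusion_tally"]}, "exclusion_tally.json")
    _csv(bundle["outcomes"], "student_outcomes.csv")

    _csv(bundle["cost_table"].reset_index(), "cost_table.csv")
    _json({p: _summary_dict(s)
           for p, s in bundle["cost_summaries"].items()}, "cost_totals.json")

    _csv(bundle["icer_table"], "icer_table.csv")
    for key, res in bundle["cea_results"].items():
        _json(res.to_dict(), f"cea_{key}.json")
        _csv(res.replicates, f"plane_{key}.csv")
        _csv(res.ceac, f"ceac_{key}.csv")

    _csv(bundle["scenario_table"], "scenario_table.csv")

    for p in paths:
        manifest.register(p)
    (out_dir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")


def _summary_dict(summary) -> dict:
    return {
        "overall_total": summary.overall_total,
        "mean_per_school": summary.mean_per_school,
        "min_per_school": summary.min_per_school,
        "max_per_school": summary.max_per_school,
        "per_school": summary.per_school,
    }


# ---------------------------------------------------------------------------
# rendered tables
# ---------------------------------------------------------------------------

def render_tables(cost_ledger: pd.DataFrame,
                  cea_results: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the cost table and the ICER table from a run's results.

    Cost table: one row per activity category (plus a total row); for each
    bearer and for the societal sum, the per-school mean/min/max in AUD.
    Row-wise, the health-service and school columns sum to the societal
    column.  ICER table: one row per outcome x perspective with point
    estimates, uncertainty intervals, and a display value that shows the
    dominance label instead of a number where the ratio is not a trade-off.
    """
    df = cost_ledger.copy()
    df["aud"] = [
        value_entry_cents(m, r, o) / 100.0
        for m, r, o in zip(df["minutes"], df["hourly_rate"],
                           df["oncost_multiplier"])]
    per_school = df.pivot_table(index="school_id", columns=["category",
                                                            "bearer"],
                                values="aud", aggfunc="sum", fill_value=0.0)

    rows = []
    for cat in list(CATEGORIES) + ["total"]:
        row = {"category": cat}
        societal = None
        for bearer in BEARERS:
            if cat == "total":
                cols = [(c, bearer) for c in CATEGORIES
                        if (c, bearer) in per_school.columns]
                vals = per_school[cols].sum(axis=1) if cols else 0.0
            else:
                vals = (per_school[(cat, bearer)]
                        if (cat, bearer) in per_school.columns
                        else pd.Series(0.0, index=per_school.index))
            row[f"{bearer}_mean"] = float(np.mean(vals))
            societal = vals if societal is None else societal + vals
        row["societal_mean"] = float(np.mean(societal))
        row["societal_min"] = float(np.min(societal))
        row["societal_max"] = float(np.max(societal))
        rows.append(row)
    cost_table = pd.DataFrame(rows)

    icer_rows = []
    for key, res in cea_results.items():
        display = (f"{res.icer.value:.2f}" if res.icer.label == "trade_off"
                   else res.icer.label)
        icer_rows.append({
            "outcome": res.outcome, "perspective": res.perspective,
            "delta_cost": res.delta_cost, "delta_effect": res.delta_effect,
            "icer": res.icer.value, "icer_display": display,
            "ui_icer_lower": res.ui_icer.get("lower"),
            "ui_icer_upper": res.ui_icer.get("upper"),
            "ui_cost_lower": res.ui_cost[0], "ui_cost_upper": res.ui_cost[1],
            "ui_effect_lower": res.ui_effect[0],
            "ui_effect_upper": res.ui_effect[1],
        })
    return cost_table, pd.DataFrame(icer_rows)
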