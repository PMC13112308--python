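"""Incremental cost-effectiveness analysis with bootstrap uncertainty.

The economic comparison is between an intervention delivered through the
online canteen and usual online ordering, at the analysis level of the
student.  The incremental cost is the difference in mean cost per student
between arms (the control arm bears no intervention cost); the incremental
effect is the between-arm difference for a dietary outcome, oriented so that
benefit is positive:

* ``energy_reduction_kj`` — a 69 kJ larger fall in intervention-arm order
  energy appears as +69;
* ``everyday_pp_increase`` — percentage-point increase in the proportion of
  'Everyday' items purchased.

The ICER is incremental cost / incremental effect, with the usual
cost-effectiveness-plane dominance logic: an intervention that costs less and
is more effective is *dominant*; one that costs more and is less effective is
*dominated*; a zero incremental effect leaves the ratio undefined.

Sampling uncertainty is quantified by a seeded non-parametric bootstrap that
resamples the analysis unit with replacement within arm, preserving arm
sizes.  Student-unit resampling (the default) holds per-school costs fixed —
each student carries their school's per-student cost share — and re-divides
by the resampled arm size; school-unit resampling is the cluster-robust
alternative, resampling whole schools with their students and costs.
Percentile (2.5th–97.5th) uncertainty intervals are reported for incremental
cost, incremental effect, and the ICER (replicate-wise ratios restricted to
the positive-effect half-plane, with out-of-quadrant replicates counted, not
silently dropped).  The cost-effectiveness acceptability curve (CEAC) gives,
for each willingness-to-pay λ, the fraction of replicates with non-negative
net monetary benefit λ·ΔE − ΔC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .costing import CostSummary, per_student_costs, summarise_costs
from .outcomes import filter_eligible, locf_impute, student_period_summary

__all__ = [
    "EffectSpec", "IcerResult", "CEAResult", "AnalysisInputs", "CEASettings",
    "build_analysis_table", "incremental_cost", "incremental_effect", "icer",
    "bootstrap_cea", "percentile_interval", "icer_interval", "ceac",
    "default_wtp_grid", "run_cea",
]

OUTCOMES = ("energy_reduction_kj", "everyday_pp_increase")
ESTIMATORS = ("diff_in_diff", "followup_difference")
UNITS = ("student", "school")

#: default willingness-to-pay grids (AUD per unit benefit), spanning the
#: decision thresholds of interest for each outcome
_WTP_GRIDS = {
    "energy_reduction_kj": (0.0, 2.0, 0.01),
    "everyday_pp_increase": (0.0, 5.0, 0.05),
}


def default_wtp_grid(outcome: str) -> np.ndarray:
    lo, hi, step = _WTP_GRIDS[outcome]
    return np.round(np.arange(lo, hi + step / 2, step), 10)


@dataclass(frozen=True)
class EffectSpec:
    """Which dietary outcome to analyse and how to estimate the effect.

    ``diff_in_diff`` compares mean change from baseline between arms (the
    default, paired with LOCF completion); ``followup_difference`` compares
    follow-up means only.  ``complete_case`` restricts the effect to students
    observed at follow-up (imputed rows ignored) — under completely-at-random
    dropout this is unbiased for the generating effect, whereas the
    LOCF-completed estimate is attenuated toward zero by the retention
    fraction.
    """

    outcome: str = "energy_reduction_kj"
    estimator: str = "diff_in_diff"
    complete_case: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")


@dataclass(frozen=True)
class IcerResult:
    """ICER point value with its cost-effectiveness-plane label.

    ``value`` is ΔC/ΔE (AUD per unit benefit) whenever ΔE != 0; ``None`` when
    the ratio is undefined.  ``label`` is one of ``trade_off`` (more costly,
    more effective), ``dominant`` (cheaper, more effective), ``dominated``
    (costlier, less effective), ``cost_saving_less_effective`` or
    ``undefined``.
    """

    value: float | None
    label: str


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """ICER with dominance logic; never divides by a zero effect."""
    if delta_effect == 0:
        return IcerResult(None, "undefined")
    value = delta_cost / delta_effect
    if delta_effect > 0:
        label = "dominant" if delta_cost < 0 else "trade_off"
    else:
        label = "dominated" if delta_cost > 0 else "cost_saving_less_effective"
    return IcerResult(value, label)


# ---------------------------------------------------------------------------
# analysis table: one row per student in the baseline cohort
# ---------------------------------------------------------------------------

def build_analysis_table(completed_outcomes: pd.DataFrame,
                         cost_ledger: pd.DataFrame) -> pd.DataFrame:
    """Assemble the student-level economic analysis table.

    One row per student with at least one eligible baseline order: arm,
    school, baseline and (LOCF-completed) follow-up values of both outcomes,
    the imputation flag, and the student's per-student intervention cost
    share under each perspective (school cost / school's analysed students;
    0 for the control arm).
    """
    wide = _pivot_outcomes(completed_outcomes)
    counts = wide.groupby("school_id", observed=True)["student_id"].count()
    for perspective, col in (("health_service", "cost_health"),
                             ("societal", "cost_societal")):
        wide[col] = 0.0
        if cost_ledger is not None and not cost_ledger.empty:
            summary = summarise_costs(cost_ledger, perspective)
            shares = per_student_costs(summary, counts.to_dict(),
                                       pooling="per_school")["per_school"]
            wide[col] = wide["school_id"].map(shares).fillna(0.0)
    return wide


def _pivot_outcomes(completed: pd.DataFrame) -> pd.DataFrame:
    base = completed[completed["period"] == "baseline"]
    fup = completed[completed["period"] == "followup"]
    keys = ["student_id", "school_id", "arm"]
    wide = base[keys + ["mean_energy", "prop_everyday"]].rename(
        columns={"mean_energy": "base_energy", "prop_everyday": "base_everyday"}
    ).merge(
        fup[keys + ["mean_energy", "prop_everyday", "imputed"]].rename(
            columns={"mean_energy": "fup_energy",
                     "prop_everyday": "fup_everyday"}),
        on=keys, how="inner",
    )
    return wide.sort_values("student_id").reset_index(drop=True)


def incremental_cost(summary: CostSummary,
                     students_per_school: Mapping[str, int],
                     pooling: str = "pooled") -> float:
    """Incremental cost per student: intervention arm mean minus control (0).

    Pooled mode divides the arm's total cost by the arm's total analysed
    students.
    """
    return per_student_costs(summary, students_per_school, pooling)["mean"]


def _arm_values(wide: pd.DataFrame, spec: EffectSpec):
    """Per-student effect contributions and the arm-combining rule.

    Returns ``(val_int, val_ctl, combine)`` where ``combine(mean_int,
    mean_ctl)`` yields the benefit-positive incremental effect.  With
    ``complete_case`` the imputed students' values are NaN and arm means use
    ``nanmean``.
    """
    col_b, col_f = (("base_energy", "fup_energy")
                    if spec.outcome == "energy_reduction_kj"
                    else ("base_everyday", "fup_everyday"))
    if spec.estimator == "diff_in_diff":
        vals = wide[col_f].to_numpy(float) - wide[col_b].to_numpy(float)
    else:
        vals = wide[col_f].to_numpy(float)
    if spec.complete_case:
        vals = np.where(wide["imputed"].to_numpy(bool), np.nan, vals)

    if spec.outcome == "energy_reduction_kj":
        combine = lambda mi, mc: mc - mi  # larger fall in intervention → +
    else:
        combine = lambda mi, mc: 100.0 * (mi - mc)  # percentage points

    is_int = (wide["arm"] == "intervention").to_numpy()
    return vals[is_int], vals[~is_int], combine


def incremental_effect(wide: pd.DataFrame, spec: EffectSpec) -> float:
    """Point incremental effect per student, oriented benefit-positive."""
    val_int, val_ctl, combine = _arm_values(wide, spec)
    if len(val_int) == 0 or len(val_ctl) == 0:
        raise ValueError("both arms need at least one analysable student")
    mi, mc = np.nanmean(val_int), np.nanmean(val_ctl)
    if np.isnan(mi) or np.isnan(mc):
        raise ValueError("an arm has no complete-case students")
    return float(combine(mi, mc))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class CEAResult:
    """Point estimates, bootstrap replicates and derived uncertainty."""

    outcome: str
    estimator: str
    perspective: str
    unit: str
    seed: int
    B: int
    n_intervention: int
    n_control: int
    delta_cost: float
    delta_effect: float
    icer: IcerResult
    replicates: pd.DataFrame  # columns: delta_cost, delta_effect, quadrant
    quadrant_counts: dict
    ui_cost: tuple
    ui_effect: tuple
    ui_icer: dict
    ceac: pd.DataFrame  # columns: wtp, probability

    def to_dict(self) -> dict:
        """JSON-serialisable summary (replicates and CEAC omitted)."""
        return {
            "outcome": self.outcome, "estimator": self.estimator,
            "perspective": self.perspective, "unit": self.unit,
            "seed": self.seed, "B": self.B,
            "n_intervention": self.n_intervention,
            "n_control": self.n_control,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer.value, "icer_label": self.icer.label,
            "ui_cost": list(self.ui_cost), "ui_effect": list(self.ui_effect),
            "ui_icer": self.ui_icer,
            "quadrant_counts": self.quadrant_counts,
        }


def _quadrants(dc: np.ndarray, de: np.ndarray) -> np.ndarray:
    """Plane quadrant per replicate; boundary points go to the closed side."""
    ne = (de > 0) & (dc > 0)
    se = (de > 0) & (dc <= 0)
    nw = (de <= 0) & (dc > 0)
    return np.where(ne, "NE", np.where(se, "SE", np.where(nw, "NW", "SW")))


def bootstrap_cea(
    wide: pd.DataFrame,
    spec: EffectSpec,
    perspective: str = "health_service",
    B: int = 2000,
    unit: str = "student",
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    level: float = 0.95,
) -> CEAResult:
    """Full CEA for one outcome/perspective with bootstrap uncertainty.

    Resampling is with replacement within arm, preserving arm sizes, on the
    chosen ``unit``; the seed stream is a single ``numpy.random.default_rng``
    drawing intervention-arm indices then control-arm indices, ``B`` rows at
    a time, so a fixed seed reproduces the replicate set exactly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if unit not in UNITS:
        raise ValueError(f"unit must be one of {UNITS}")
    cost_col = {"health_service": "cost_health",
                "societal": "cost_societal"}.get(perspective)
    if cost_col is None:
        raise ValueError(
            "perspective must be 'health_service' or 'societal'")

    val_int, val_ctl, combine = _arm_values(wide, spec)
    is_int = (wide["arm"] == "intervention").to_numpy()
    cost_int = wide.loc[is_int, cost_col].to_numpy(float)
    n_i, n_c = len(val_int), len(val_ctl)
    if n_i == 0 or n_c == 0:
        raise ValueError("both arms need at least one analysable student")

    point_dc = float(cost_int.mean())
    point_de = incremental_effect(wide, spec)

    rng = np.random.default_rng(seed)
    if unit == "student":
        idx_i = rng.integers(0, n_i, size=(B, n_i))
        idx_c = rng.integers(0, n_c, size=(B, n_c))
        dc = cost_int[idx_i].mean(axis=1)
        de = combine(np.nanmean(val_int[idx_i], axis=1),
                     np.nanmean(val_ctl[idx_c], axis=1))
    else:
        dc, de = _school_bootstrap(wide, cost_col, val_int, val_ctl, combine,
                                   B, rng)

    dc = np.asarray(dc, float)
    de = np.asarray(de, float)
    quad = _quadrants(dc, de)
    counts = {q: int((quad == q).sum()) for q in ("NE", "SE", "NW", "SW")}

    grid = default_wtp_grid(spec.outcome) if wtp_grid is None else np.asarray(
        wtp_grid, float)
    return CEAResult(
        outcome=spec.outcome, estimator=spec.estimator,
        perspective=perspective, unit=unit, seed=seed, B=B,
        n_intervention=n_i, n_control=n_c,
        delta_cost=point_dc, delta_effect=point_de,
        icer=icer(point_dc, point_de),
        replicates=pd.DataFrame({"delta_cost": dc, "delta_effect": de,
                                 "quadrant": quad}),
        quadrant_counts=counts,
        ui_cost=percentile_interval(dc, level),
        ui_effect=percentile_interval(de, level),
        ui_icer=icer_interval(dc, de, level),
        ceac=ceac(dc, de, grid),
    )


def _school_bootstrap(wide, cost_col, val_int, val_ctl, combine, B, rng):
    """Cluster bootstrap: resample schools with their students and costs."""
    is_int = (wide["arm"] == "intervention").to_numpy()
    int_pos = np.flatnonzero(is_int)
    ctl_pos = np.flatnonzero(~is_int)
    # positions here index into val_int / val_ctl (arm-local arrays)
    local = np.empty(len(wide), dtype=int)
    local[int_pos] = np.arange(len(int_pos))
    local[ctl_pos] = np.arange(len(ctl_pos))

    def arm_groups(pos):
        sub = wide.iloc[pos]
        groups = [local[pos[(sub["school_id"] == s).to_numpy()]]
                  for s in sub["school_id"].unique()]
        return groups

    groups_i = arm_groups(int_pos)
    groups_c = arm_groups(ctl_pos)
    school_cost = np.array(
        [wide.loc[is_int, cost_col].to_numpy()[g].sum() for g in groups_i])

    pick_i = rng.integers(0, len(groups_i), size=(B, len(groups_i)))
    pick_c = rng.integers(0, len(groups_c), size=(B, len(groups_c)))
    dc = np.empty(B)
    de = np.empty(B)
    for b in range(B):
        sel_i = np.concatenate([groups_i[k] for k in pick_i[b]])
        sel_c = np.concatenate([groups_c[k] for k in pick_c[b]])
        dc[b] = school_cost[pick_i[b]].sum() / len(sel_i)
        de[b] = combine(np.nanmean(val_int[sel_i]),
                        np.nanmean(val_ctl[sel_c]))
    return dc, de


# ---------------------------------------------------------------------------
# intervals and acceptability
# ---------------------------------------------------------------------------

def percentile_interval(replicates: np.ndarray,
                        level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation."""
    replicates = np.asarray(replicates, float)
    if replicates.size < 2:
        raise ValueError("need at least 2 replicates for an interval")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    alpha = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(replicates, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def icer_interval(delta_cost: np.ndarray, delta_effect: np.ndarray,
                  level: float = 0.95) -> dict:
    """Percentile interval of replicate-wise ICER ratios.

    Ratios are formed only on the positive-effect half-plane (trade-off and
    dominant quadrants); replicates elsewhere are counted in
    ``n_out_of_quadrant`` and reported, not silently dropped.  If no
    replicate has a positive effect the interval is flagged undefined.
    """
    dc = np.asarray(delta_cost, float)
    de = np.asarray(delta_effect, float)
    mask = de > 0
    out = int((~mask).sum())
    if mask.sum() < 2:
        return {"defined": False, "lower": None, "upper": None,
                "n_used": int(mask.sum()), "n_out_of_quadrant": out,
                "level": level}
    lo, hi = percentile_interval(dc[mask] / de[mask], level)
    return {"defined": True, "lower": lo, "upper": hi,
            "n_used": int(mask.sum()), "n_out_of_quadrant": out,
            "level": level}


# ---------------------------------------------------------------------------
# end-to-end helper: raw order table + ledger -> CEAResult
# ---------------------------------------------------------------------------

@dataclass
class AnalysisInputs:
    """Raw inputs of one economic analysis run.

    ``orders`` is the item-level order table (unfiltered), ``cost_ledger``
    the activity ledger for the costed arm, ``per_protocol_schools`` the
    intervention schools where delivery was complete (used by the
    per-protocol sensitivity scenario).
    """

    orders: pd.DataFrame
    cost_ledger: pd.DataFrame
    per_protocol_schools: list | None = None


@dataclass
class CEASettings:
    """Bootstrap and estimator settings shared across an analysis run."""

    spec: EffectSpec = field(default_factory=EffectSpec)
    perspective: str = "health_service"
    B: int = 2000
    unit: str = "student"
    seed: int = 0
    wtp_grid: np.ndarray | None = None
    level: float = 0.95


def run_cea(inputs: AnalysisInputs, settings: CEASettings,
            effect_override: float | None = None) -> CEAResult:
    """Filter orders, summarise outcomes, LOCF-complete, cost and bootstrap.

    ``effect_override`` replaces the estimated incremental effect with an
    externally supplied value (a fixed quantity across replicates), so the
    uncertainty interval then reflects cost variation only.
    """
    eligible, _ = filter_eligible(inputs.orders)
    summaries = student_period_summary(eligible)
    completed = locf_impute(summaries)
    wide = build_analysis_table(completed, inputs.cost_ledger)
    result = bootstrap_cea(wide, settings.spec, settings.perspective,
                           settings.B, settings.unit, settings.seed,
                           settings.wtp_grid, settings.level)
    if effect_override is not None:
        result = _with_fixed_effect(result, effect_override, settings.level)
    return result


def _with_fixed_effect(res: CEAResult, effect: float,
                       level: float) -> CEAResult:
    """Rebuild a result holding the incremental effect at a fixed value."""
    dc = res.replicates["delta_cost"].to_numpy()
    de = np.full_like(dc, float(effect))
    quad = _quadrants(dc, de)
    grid = res.ceac["wtp"].to_numpy()
    return CEAResult(
        outcome=res.outcome, estimator="override", perspective=res.perspective,
        unit=res.unit, seed=res.seed, B=res.B,
        n_intervention=res.n_intervention, n_control=res.n_control,
        delta_cost=res.delta_cost, delta_effect=float(effect),
        icer=icer(res.delta_cost, float(effect)),
        replicates=pd.DataFrame({"delta_cost": dc, "delta_effect": de,
                                 "quadrant": quad}),
        quadrant_counts={q: int((quad == q).sum())
                         for q in ("NE", "SE", "NW", "SW")},
        ui_cost=percentile_interval(dc, level),
        ui_effect=(float(effect), float(effect)),
        ui_icer=icer_interval(dc, de, level),
        ceac=ceac(dc, de, grid),
    )


def ceac(delta_cost: np.ndarray, delta_effect: np.ndarray,
         wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve on a willingness-to-pay grid.

    P(cost-effective at λ) = fraction of replicates with net monetary benefit
    λ·ΔE − ΔC >= 0.
    """
    grid = np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("WTP grid is empty")
    if (grid < 0).any():
        raise ValueError("WTP values must be >= 0")
    dc = np.asarray(delta_cost, float)
    de = np.asarray(delta_effect, float)
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid, "probability": prob})
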