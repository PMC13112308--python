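# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic data can and cannot show about the real trial.

## Economic evaluation model

The evaluation compares an online-canteen choice-architecture intervention
with usual online ordering in a two-arm cluster randomised design (schools
randomised; students nested in schools; two 8-week observation periods
12 months apart; a 16-month horizon, short enough that no discounting is
applied). The unit of analysis is the student with at least one eligible
baseline order.

**Costing.** Delivery costs are micro-costed: every activity is a ledger
entry `(school, category, bearer, minutes, hourly rate, oncost multiplier)`
with category ∈ {collect_menu, assess_menu, execute_strategies} and bearer ∈
{health_service, school}. An entry's value is `minutes/60 × rate × oncost`,
rounded half-up to the cent; aggregation beyond the entry is exact
integer-cent arithmetic so that the category partition, the bearer partition
and the school total reconcile to the cent. The health-service perspective
keeps health-service entries; the societal perspective adds the school's
opportunity costs. Displaced usual-practice costs are taken as zero, per the
trial design. Intervention development and research costs are out of scope.

**Per-student cost.** The phrase "cost per school divided by the number of
students" is ambiguous between a pooled arm-level division and a per-school
division averaged across schools. Both are implemented; under
student-weighted averaging they coincide algebraically
(Σ_s (c_s/n_s)·n_s / Σ_s n_s = Σc/Σn), and the pooled form — arm total cost
over arm total analysed students — is the default used in the ICER, the
convention for arm-level incremental costs. The control arm bears no
intervention cost.

**Effects.** Two outcomes, both oriented so benefit is positive:
energy reduction per lunch order (kJ) and the percentage-point increase in
'Everyday' items purchased. Two estimators are exposed because the source
analysis does not state which aggregation fed its ratio:

* `diff_in_diff` (default): mean within-student change from baseline,
  differenced between arms;
* `followup_difference`: difference in follow-up means only.

Missing follow-up is completed by LOCF, which forces an imputed student's
change to exactly zero. Under completely-at-random dropout this attenuates
the difference-in-differences estimand to `retention × true effect`
(≈ 0.82 × 69 ≈ 57 kJ at the defaults) — the deliberately conservative
property of LOCF, which the tests assert. A `complete_case` switch
restricts the effect to students observed at follow-up; under MCAR dropout
it is unbiased for the generating effect and is what the parameter-recovery
tests check against the truth.

**ICER and uncertainty.** ICER = ΔC/ΔE with plane logic: `dominant`
(ΔC < 0, ΔE > 0), `dominated` (ΔC > 0, ΔE < 0), `undefined` at ΔE = 0
(never a numeric ratio). Uncertainty is a seeded non-parametric bootstrap,
default B = 2000 (comfortably above the conventional >1000 floor),
resampling within arm with arm sizes preserved:

* *student* unit (default): each intervention student carries their
  school's per-student cost share, so per-school costs stay fixed and the
  replicate cost is the mean over the resampled arm; effects are recomputed
  from the resampled students. The costs in the source evaluation were
  likewise not cluster-adjusted.
* *school* unit: whole schools are resampled with their students and
  costs — the cluster-robust option.

Intervals are empirical 2.5th–97.5th percentiles with linear interpolation
(level configurable; 95 % is assumed since none is stated for the original
intervals). The ICER interval uses replicate-wise ratios restricted to the
positive-effect half-plane; replicates outside it are counted and reported,
never silently dropped. The CEAC evaluates P(λ·ΔE − ΔC ≥ 0) on a WTP grid —
default $0–$2 step $0.01 per kJ and $0–$5 step $0.05 per percentage point,
spanning the decision thresholds of interest ($0.20/kJ, $1.20/pp). Plane
quadrant counts always sum to B (boundary replicates are assigned to the
closed side deterministically).

**Sensitivity engine.** Scenarios modify deep copies of the inputs (wage
overrides by bearer, category removal — never all three, school subsetting
including the per-protocol set) and re-run the full pipeline under common
random numbers, so scenario-minus-baseline differences are free of bootstrap
noise. A per-protocol run recomputes the effect from the subset's own data
by default; `effect_override` injects an externally estimated effect (e.g. a
mixed-model estimate such as −89 kJ) as a fixed quantity, leaving only cost
uncertainty in the interval.

## Synthetic-data generator

Because the trial's order-level data are proprietary to the canteen
provider, all analyses run on synthetic trials. The generator reproduces
the *statistical structure the economic analysis consumes*, not canteen
physics:

| parameter | default | anchor |
|---|---|---|
| schools | 9 intervention + 8 control | study design |
| students/school | NB(mean 130, disp 12), ≥1 | calibration (→ ~2200 students) |
| orders/student/period | NB(mean 4, disp 3); ≥1 at baseline | calibration |
| order energy | zero-truncated Normal(1400, 450) kJ, 40 % of SD between students | calibration |
| energy effect | −69 kJ on intervention follow-up orders | study estimate |
| 'Everyday' probability | 0.70 baseline; odds × 1.7 at intervention follow-up | OR 1.7 ⇒ +9.8 pp |
| follow-up retention | 0.82, completely at random | study figure |
| items/order | 1 + Poisson(1.5), capped at 15 | calibration |
| ineligible orders | 5 %, mechanism uniform over web/break/day/oversize | calibration |
| per-school costs | bearer means $518 + $50, school factor U(0.55, 1.45) | study aggregates; spread spans ≈ $343–$806 |
| cost category split | health $250/$156/$112; school $30/$5/$15 | only the $112 execute mean and bearer totals are anchored |

Modelling choices: order energy is drawn per order (item energies are a
flat-Dirichlet split of the total) because the analysis consumes order
totals; the intervention effect is a pure location shift, matching an
additive between-group difference; item classifications are independent
Bernoulli draws with the non-'Everyday' remainder split 75/25 between
'Occasional' and 'Should not be sold'; dropout is MCAR so the LOCF bias
direction is known and testable. All draws flow through one seeded
generator; a fixed config + seed is bit-reproducible.

What the generator does **not** emulate: menu/recipe structure and item
price–nutrient correlation, seasonality, within-student longitudinal
correlation beyond a shared student mean, school-level effect
heterogeneity, and informative dropout. Consequently, passing tests show
that the *estimators and machinery* behave correctly under the assumed
structure (effects and odds ratios are recovered, intervals are calibrated
against brute-force resampling, accounting identities hold); they do not
show that the published point estimates would be reproduced from the real
data, which are not available. In particular the published ICERs
($0.06/kJ, $0.46/pp health-service) are not algebraically recoverable from
the published aggregates (518 × 9 / 1359 / 69 ≈ $0.05/kJ), so the package
exposes every estimator/denominator switch rather than asserting one of
them reproduces the print.

## Numerical choices and degenerate inputs

* Money: half-up rounding at the entry level, exact cent integers
  afterwards; summaries expose floats derived from cent sums.
* Percentiles: NumPy linear interpolation; `level=1` degenerates to
  (min, max); constant replicate sets give zero-width intervals.
* Zero-energy orders have undefined energy shares; they are flagged and
  excluded from share means (energy means still include them).
* Exclusion tallies use the fixed precedence channel → break → day → size,
  one reason per order, so tallies are deterministic and sum with the
  eligible count to the order total.
* Students with follow-up but no baseline outcomes cannot be carried
  forward; they are excluded with a logged warning. Students absent at
  baseline are outside the analysis set by definition.
* An effect of exactly zero yields an explicit `undefined` ICER, and an
  empty WTP grid, a negative λ, B < 1, unknown perspectives/units/labels
  all fail fast with messages naming the offending value.

## Problem sizes used in the shipped analyses

The numbered scripts and the acceptance run use the default generator size
(~2000 analysed students, ~14 000 eligible orders) with B = 2000.
Parameter-recovery checks run at ~290 students per school (≥ 2000 per arm)
so that 3-standard-error bands are tight around the generating values;
null-calibration checks average 50 small replicate trials. These sizes were
chosen to make Monte-Carlo error small relative to the effects being
recovered while keeping each analysis a matter of seconds.

## Known limitations

* The cost generator's category split is invented beyond the published
  bearer totals; scenario magnitudes that depend on that split (e.g. the
  exact ICER drop from removing menu assessment) are illustrative, though
  their directions are guaranteed by construction.
* LOCF + difference-in-differences deliberately reproduces LOCF's
  conservative bias; users wanting unbiased effect recovery under MCAR
  should use `complete_case=True` or `followup_difference` on observed
  students.
* The student-unit bootstrap ignores clustering by design (matching the
  original cost analysis); school-unit resampling with 17 clusters is
  available but percentile intervals from so few clusters are themselves
  noisy.
* No QALY modelling, currency conversion, inflation indexing, Fieller or
  delta-method intervals, or EVPI.
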