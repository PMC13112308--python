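# Default analysis configuration.
#
# The `trial` block parameterises the synthetic cluster-trial generator.
# Anchored values (school counts, effect sizes, retention, bearer cost
# means) emulate the published study conditions.  The order-energy mean/SD,
# order- and item-count distributions and the category split of costs are
# UNANCHORED calibration choices: the source trial does not report them.
trial:
  n_intervention_schools: 9
  n_control_schools: 8
  students_per_school_mean: 130.0        # unanchored; yields ~2200 students
  students_per_school_dispersion: 12.0   # unanchored
  orders_per_student_mean: 4.0           # unanchored (per 8-week period)
  orders_per_student_dispersion: 3.0     # unanchored
  baseline_order_energy_mean: 1400.0     # kJ; unanchored
  baseline_order_energy_sd: 450.0        # kJ; unanchored
  energy_between_student_frac: 0.4       # unanchored
  energy_effect: 69.0                    # kJ fall in intervention follow-up
  everyday_baseline_prob: 0.70           # so OR 1.7 implies +9.8 pp
  everyday_odds_ratio: 1.7
  occasional_share_of_rest: 0.75         # unanchored
  followup_retention: 0.82
  items_per_order_mean: 2.5              # unanchored
  ineligible_order_rate: 0.05            # unanchored
  cost_mean_health: 518.0                # AUD per school
  cost_mean_school: 50.0                 # AUD per school
  cost_spread: 0.45                      # spans roughly the $343-$806 range
  n_per_protocol_schools: 5
  seed: 1

cea:
  B: 2000
  unit: student          # or "school" for the cluster-robust bootstrap
  level: 0.95

scenarios:
  - name: higher_canteen_wages
    wage_overrides:
      school: 32.40      # 1.5x the level-2 award rate
  - name: no_menu_assessment
    drop_categories: [assess_menu]
  - name: per_protocol
    school_subset: per_protocol
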