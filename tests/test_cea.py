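"""ICER logic, bootstrap, percentile intervals, plane and CEAC."""

import numpy as np
import pandas as pd
import pytest

from canteen_cea.cea import (EffectSpec, bootstrap_cea, ceac, icer,
                             icer_interval, incremental_effect,
                             percentile_interval)


def wide_frame(rows):
    cols = ["student_id", "school_id", "arm", "base_energy", "base_everyday",
            "fup_energy", "fup_everyday", "imputed", "cost_health",
            "cost_societal"]
    return pd.DataFrame(rows, columns=cols)


def toy_wide():
    """Six students, hand-checkable: intervention falls 69 kJ, control flat."""
    rows = []
    for i, (base, fup, cost) in enumerate(
            [(1500.0, 1431.0, 3.0), (1600.0, 1531.0, 3.5),
             (1400.0, 1331.0, 4.0)]):
        rows.append((f"I-{i}", "I01", "intervention", base, 0.7, fup, 0.8,
                     False, cost, cost + 0.5))
    for i, base in enumerate([1450.0, 1550.0, 1500.0]):
        rows.append((f"C-{i}", "C01", "control", base, 0.7, base, 0.7,
                     False, 0.0, 0.0))
    return wide_frame(rows)


class TestIcer:
    @pytest.mark.parametrize("dc,de,value,label", [
        (4.14, 69.0, 0.06, "trade_off"),
        (-1.0, 5.0, -0.2, "dominant"),
        (2.0, -1.0, -2.0, "dominated"),
        (-2.0, -1.0, 2.0, "cost_saving_less_effective"),
    ])
    def test_plane_quadrants(self, dc, de, value, label):
        res = icer(dc, de)
        assert res.label == label
        assert res.value == pytest.approx(value)

    def test_zero_effect_is_undefined_never_a_ratio(self):
        res = icer(2.0, 0.0)
        assert res.value is None and res.label == "undefined"


class TestEffect:
    def test_identical_arms_give_zero(self):
        rows = [("I-1", "I01", "intervention", 1500.0, 0.7, 1400.0, 0.7,
                 False, 3.0, 3.5),
                ("C-1", "C01", "control", 1500.0, 0.7, 1400.0, 0.7,
                 False, 0.0, 0.0)]
        wide = wide_frame(rows)
        for est in ("diff_in_diff", "followup_difference"):
            spec = EffectSpec(outcome="energy_reduction_kj", estimator=est)
            assert incremental_effect(wide, spec) == pytest.approx(0.0)

    def test_forced_69_kj_fall_under_both_estimators(self):
        wide = toy_wide()
        for est in ("diff_in_diff", "followup_difference"):
            spec = EffectSpec(outcome="energy_reduction_kj", estimator=est)
            assert incremental_effect(wide, spec) == pytest.approx(69.0)

    def test_everyday_effect_in_percentage_points(self):
        spec = EffectSpec(outcome="everyday_pp_increase")
        assert incremental_effect(toy_wide(), spec) == pytest.approx(10.0)

    def test_empty_arm_is_an_error(self):
        wide = toy_wide()
        with pytest.raises(ValueError, match="arm"):
            incremental_effect(wide[wide["arm"] == "control"], EffectSpec())

    def test_complete_case_ignores_imputed_rows(self):
        wide = toy_wide()
        extra = wide_frame([("I-9", "I01", "intervention", 1500.0, 0.7,
                             1500.0, 0.7, True, 3.0, 3.5)])
        both = pd.concat([wide, extra], ignore_index=True)
        locf = incremental_effect(both, EffectSpec())
        cc = incremental_effect(both, EffectSpec(complete_case=True))
        assert cc == pytest.approx(69.0)
        assert locf < cc  # the imputed zero-change row attenuates


class TestPercentiles:
    def test_one_to_hundred_interval(self):
        lo, hi = percentile_interval(np.arange(1, 101, dtype=float))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_replicates(self):
        assert percentile_interval(np.full(50, 7.0)) == (7.0, 7.0)

    def test_level_one_gives_range(self):
        x = np.array([3.0, 1.0, 9.0])
        assert percentile_interval(x, level=1.0) == (1.0, 9.0)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            percentile_interval(np.array([1.0]))

    def test_icer_interval_reports_out_of_quadrant(self):
        dc = np.array([1.0, 2.0, 3.0, 4.0])
        de = np.array([1.0, 1.0, -1.0, 0.0])
        out = icer_interval(dc, de)
        assert out["defined"] and out["n_used"] == 2
        assert out["n_out_of_quadrant"] == 2

    def test_icer_interval_undefined_when_no_positive_effect(self):
        out = icer_interval(np.array([1.0, 2.0]), np.array([-1.0, 0.0]))
        assert not out["defined"] and out["lower"] is None


class TestCeac:
    def test_hand_enumerated_example(self):
        dc = np.array([0.5, 2.0, 1.0, 3.0])
        de = np.array([1.0, 1.0, 2.0, 1.0])
        curve = ceac(dc, de, np.array([1.0]))
        assert curve["probability"].iloc[0] == pytest.approx(0.5)

    def test_limits_at_zero_and_large_wtp(self):
        rng = np.random.default_rng(0)
        dc = rng.normal(1.0, 2.0, 500)
        de = rng.normal(0.5, 1.0, 500)
        curve = ceac(dc, de, np.array([0.0, 1e9]))
        assert curve["probability"].iloc[0] == pytest.approx(
            (dc <= 0).mean())
        assert curve["probability"].iloc[1] == pytest.approx(
            ((de > 0) | ((de == 0) & (dc <= 0))).mean(), abs=1e-3)

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(1)
        dc = rng.normal(1.0, 1.0, 400)
        de = np.abs(rng.normal(1.0, 0.5, 400)) + 1e-6
        grid = np.linspace(0, 10, 101)
        probs = ceac(dc, de, grid)["probability"].to_numpy()
        assert (np.diff(probs) >= 0).all()

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ceac(np.array([1.0]), np.array([1.0]), np.array([-0.5]))


class TestBootstrap:
    def test_fixed_seed_reproduces_replicates(self):
        wide = toy_wide()
        a = bootstrap_cea(wide, EffectSpec(), B=200, seed=42)
        b = bootstrap_cea(wide, EffectSpec(), B=200, seed=42)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_degenerate_data_give_zero_width_intervals(self):
        rows = [(f"I-{i}", "I01", "intervention", 1500.0, 0.7, 1400.0, 0.8,
                 False, 3.0, 3.5) for i in range(4)]
        rows += [(f"C-{i}", "C01", "control", 1500.0, 0.7, 1500.0, 0.7,
                  False, 0.0, 0.0) for i in range(4)]
        res = bootstrap_cea(wide_frame(rows), EffectSpec(), B=300, seed=1)
        assert res.ui_cost == (3.0, 3.0)
        assert res.ui_effect == (100.0, 100.0)
        assert (res.replicates["delta_cost"] == 3.0).all()
        assert res.ui_icer["lower"] == pytest.approx(0.03)
        assert res.ui_icer["upper"] == pytest.approx(0.03)

    def test_quadrant_counts_sum_to_B(self):
        res = bootstrap_cea(toy_wide(), EffectSpec(), B=257, seed=3)
        assert sum(res.quadrant_counts.values()) == 257

    def test_replicate_mean_near_point_estimate(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(6):
            base = 1500 + rng.normal(0, 100)
            rows.append((f"I-{i}", "I01", "intervention", base, 0.7,
                         base - 69 + rng.normal(0, 120), 0.8, False, 3.0, 3.5))
        for i in range(6):
            base = 1500 + rng.normal(0, 100)
            rows.append((f"C-{i}", "C01", "control", base, 0.7,
                         base + rng.normal(0, 120), 0.7, False, 0.0, 0.0))
        wide = wide_frame(rows)
        res = bootstrap_cea(wide, EffectSpec(), B=2000, seed=5)
        de = res.replicates["delta_effect"]
        se = de.std()
        assert se > 0
        assert abs(de.mean() - res.delta_effect) < 3 * se / np.sqrt(len(de))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bootstrap_cea(toy_wide(), EffectSpec(), B=0)
        with pytest.raises(ValueError):
            bootstrap_cea(toy_wide(), EffectSpec(), unit="class")
        with pytest.raises(ValueError):
            bootstrap_cea(toy_wide(), EffectSpec(), perspective="payer")

    def test_matches_independent_brute_force_oracle(self):
        """Replicates, UIs and CEAC agree exactly with a separately coded
        bootstrap that consumes the same seed stream on a 6-student set."""
        wide = toy_wide()
        B, seed = 500, 9
        res = bootstrap_cea(wide, EffectSpec(), B=B, seed=seed)

        # --- oracle: plain-python resampling, same index stream ----------
        int_rows = wide[wide["arm"] == "intervention"].reset_index(drop=True)
        ctl_rows = wide[wide["arm"] == "control"].reset_index(drop=True)
        n_i, n_c = len(int_rows), len(ctl_rows)
        rng = np.random.default_rng(seed)
        idx_i = rng.integers(0, n_i, size=(B, n_i))
        idx_c = rng.integers(0, n_c, size=(B, n_c))
        oracle_dc, oracle_de = [], []
        for b in range(B):
            cost = [int_rows["cost_health"][j] for j in idx_i[b]]
            ch_i = [int_rows["fup_energy"][j] - int_rows["base_energy"][j]
                    for j in idx_i[b]]
            ch_c = [ctl_rows["fup_energy"][j] - ctl_rows["base_energy"][j]
                    for j in idx_c[b]]
            oracle_dc.append(sum(cost) / n_i)
            oracle_de.append(sum(ch_c) / n_c - sum(ch_i) / n_i)
        oracle_dc = np.array(oracle_dc)
        oracle_de = np.array(oracle_de)

        np.testing.assert_allclose(res.replicates["delta_cost"], oracle_dc,
                                   rtol=0, atol=1e-12)
        np.testing.assert_allclose(res.replicates["delta_effect"], oracle_de,
                                   rtol=0, atol=1e-9)
        assert res.ui_cost == pytest.approx(
            tuple(np.percentile(oracle_dc, [2.5, 97.5])))
        assert res.ui_effect == pytest.approx(
            tuple(np.percentile(oracle_de, [2.5, 97.5])))
        # CEAC from first principles on the oracle replicates
        for _, row in res.ceac.iloc[::25].iterrows():
            manual = np.mean(row["wtp"] * oracle_de - oracle_dc >= 0)
            assert row["probability"] == pytest.approx(manual)

    def test_school_unit_resamples_clusters(self):
        rng = np.random.default_rng(2)
        rows = []
        for s, cost in (("I01", 2.0), ("I02", 4.0), ("I03", 6.0)):
            for i in range(5):
                base = 1500 + rng.normal(0, 50)
                rows.append((f"{s}-{i}", s, "intervention", base, 0.7,
                             base - 69, 0.8, False, cost, cost))
        for s in ("C01", "C02", "C03"):
            for i in range(5):
                base = 1500 + rng.normal(0, 50)
                rows.append((f"{s}-{i}", s, "control", base, 0.7, base, 0.7,
                             False, 0.0, 0.0))
        wide = wide_frame(rows)
        res = bootstrap_cea(wide, EffectSpec(), B=400, unit="school", seed=4)
        # every replicate's cost is an average over resampled school costs
        assert res.replicates["delta_cost"].between(2.0, 6.0).all()
        assert sum(res.quadrant_counts.values()) == 400
        res2 = bootstrap_cea(wide, EffectSpec(), B=400, unit="school", seed=4)
        pd.testing.assert_frame_equal(res.replicates, res2.replicates)
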