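"""Eligibility filtering, per-student dietary outcomes and LOCF."""

import logging

import numpy as np
import pandas as pd
import pytest

from canteen_cea import generate_trial
from canteen_cea.outcomes import (OrderItem, OrderRecord, energy_shares,
                                  filter_eligible, locf_impute, order_energy,
                                  records_to_frame, student_period_summary)


def make_order(oid=1, n_items=1, energy=500.0, **kw):
    items = tuple(OrderItem(energy_kj=energy) for _ in range(n_items))
    return OrderRecord(order_id=str(oid), student_id=kw.pop("student", "A"),
                       school_id="I01", arm="intervention",
                       period=kw.pop("period", "baseline"), items=items, **kw)


class TestFilter:
    def test_size_boundary_is_inclusive_at_fifteen(self):
        df = records_to_frame([make_order(1, n_items=15),
                               make_order(2, n_items=16)])
        eligible, tally = filter_eligible(df)
        assert set(eligible["order_id"]) == {"1"}
        assert tally == {"channel": 0, "break": 0, "day": 0, "size": 1,
                         "eligible": 1}

    def test_each_rule_excludes(self):
        df = records_to_frame([
            make_order(1, channel="web"),
            make_order(2, break_type="other"),
            make_order(3, day_type="special"),
            make_order(4, n_items=16),
            make_order(5),
        ])
        _, tally = filter_eligible(df)
        assert tally == {"channel": 1, "break": 1, "day": 1, "size": 1,
                         "eligible": 1}

    def test_precedence_channel_before_size(self):
        """A web order with 16 items is tallied once, under 'channel'."""
        df = records_to_frame([make_order(1, n_items=16, channel="web")])
        _, tally = filter_eligible(df)
        assert tally["channel"] == 1 and tally["size"] == 0

    def test_idempotent(self, small_trial):
        once, tally1 = filter_eligible(small_trial.orders)
        twice, tally2 = filter_eligible(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))
        assert tally2["eligible"] == tally1["eligible"]
        assert sum(tally2[r] for r in ("channel", "break", "day", "size")) == 0

    def test_empty_input(self):
        eligible, tally = filter_eligible(pd.DataFrame(
            columns=["order_id", "channel"]))
        assert eligible.empty and tally["eligible"] == 0


class TestOrderArithmetic:
    def test_order_energy_is_item_sum(self):
        o = OrderRecord("1", "A", "I01", "intervention", "baseline",
                        tuple(OrderItem(e) for e in (800.0, 450.0, 250.0)))
        assert order_energy(o) == 1500.0
        assert order_energy(make_order(energy=0.0)) == 0.0

    def test_energy_share_conversions(self):
        o = OrderRecord("1", "A", "I01", "intervention", "baseline",
                        (OrderItem(1850.0, satfat_g=10.0, sugar_g=0.0),))
        satfat, sugar = energy_shares(o)
        assert satfat == pytest.approx(0.2)  # 37 x 10 / 1850
        assert sugar == 0.0
        o2 = OrderRecord("2", "A", "I01", "intervention", "baseline",
                         (OrderItem(1700.0, sugar_g=20.0),))
        assert energy_shares(o2)[1] == pytest.approx(0.2)  # 17 x 20 / 1700

    def test_zero_energy_shares_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            energy_shares(make_order(energy=0.0))

    def test_negative_nutrients_rejected(self):
        with pytest.raises(ValueError):
            OrderItem(energy_kj=-1.0)


class TestStudentSummary:
    def test_mean_energy_over_orders(self, toy_items):
        out = student_period_summary(toy_items)
        a_base = out.query("student_id == 'A' and period == 'baseline'").iloc[0]
        assert a_base["mean_energy"] == pytest.approx(1500.0)  # (1000+2000)/2
        assert a_base["n_orders"] == 2

    def test_classification_proportions_pool_items_across_orders(self, toy_items):
        out = student_period_summary(toy_items)
        a_base = out.query("student_id == 'A' and period == 'baseline'").iloc[0]
        # items E,E,O and E,S pooled -> 3 of 5 Everyday
        assert a_base["prop_everyday"] == pytest.approx(3 / 5)
        assert a_base["prop_occasional"] == pytest.approx(1 / 5)
        assert a_base["prop_should_not"] == pytest.approx(1 / 5)

    def test_single_order_summary_is_identity(self, toy_items):
        out = student_period_summary(toy_items)
        a_fup = out.query("student_id == 'A' and period == 'followup'").iloc[0]
        assert a_fup["mean_energy"] == pytest.approx(900.0)
        assert a_fup["prop_everyday"] == 1.0

    def test_proportions_sum_to_one(self, small_trial):
        eligible, _ = filter_eligible(small_trial.orders)
        out = student_period_summary(eligible)
        total = (out["prop_everyday"] + out["prop_occasional"]
                 + out["prop_should_not"])
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_energy_shares_within_unit_interval(self, small_trial):
        eligible, _ = filter_eligible(small_trial.orders)
        out = student_period_summary(eligible)
        assert out["energy_share_satfat"].between(0, 1).all()
        assert out["energy_share_sugar"].between(0, 1).all()


class TestLocf:
    def outcomes_frame(self, rows):
        cols = ["student_id", "school_id", "arm", "period", "n_orders",
                "mean_energy", "prop_everyday", "prop_occasional",
                "prop_should_not", "energy_share_satfat",
                "energy_share_sugar", "imputed"]
        return pd.DataFrame(rows, columns=cols)

    def test_baseline_carried_forward(self):
        df = self.outcomes_frame([
            ("A", "I01", "intervention", "baseline", 2, 1500.0,
             0.6, 0.2, 0.2, 0.1, 0.2, False),
        ])
        completed = locf_impute(df)
        fup = completed.query("period == 'followup'").iloc[0]
        assert fup["mean_energy"] == 1500.0
        assert fup["prop_everyday"] == 0.6
        assert bool(fup["imputed"]) is True

    def test_observed_followup_untouched(self):
        df = self.outcomes_frame([
            ("A", "I01", "intervention", "baseline", 1, 1500.0,
             0.6, 0.2, 0.2, 0.1, 0.2, False),
            ("A", "I01", "intervention", "followup", 1, 1200.0,
             0.8, 0.1, 0.1, 0.1, 0.2, False),
        ])
        completed = locf_impute(df)
        fup = completed.query("period == 'followup'").iloc[0]
        assert fup["mean_energy"] == 1200.0
        assert not fup["imputed"]

    def test_followup_without_baseline_excluded_with_warning(self, caplog):
        df = self.outcomes_frame([
            ("Z", "I01", "intervention", "followup", 1, 900.0,
             1.0, 0.0, 0.0, 0.1, 0.2, False),
        ])
        with caplog.at_level(logging.WARNING):
            completed = locf_impute(df)
        assert completed.empty
        assert "no baseline" in caplog.text

    def test_full_retention_dataset_has_no_imputation(self, small_config):
        cfg = small_config.model_copy(
            update={"followup_retention": 1.0, "ineligible_order_rate": 0.0})
        eligible, _ = filter_eligible(generate_trial(cfg).orders)
        completed = locf_impute(student_period_summary(eligible))
        assert not completed["imputed"].any()

    def test_imputed_students_contribute_exactly_zero_change(self, small_trial):
        """LOCF's conservative no-change property, student by student."""
        eligible, _ = filter_eligible(small_trial.orders)
        completed = locf_impute(student_period_summary(eligible))
        wide = completed.pivot_table(index="student_id", columns="period",
                                     values="mean_energy")
        imputed_ids = completed.loc[completed["imputed"], "student_id"]
        assert len(imputed_ids) > 0
        change = wide.loc[imputed_ids, "followup"] - wide.loc[imputed_ids,
                                                              "baseline"]
        assert (change == 0.0).all()
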