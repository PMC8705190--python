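"""Cohort I/O, validation, exclusion cascade, truncation and aggregation."""

import numpy as np
import pandas as pd
import pytest

from mbrcea.cohort import (
    aggregate_periods,
    adjust_to_reference_euros,
    apply_exclusions,
    pretreatment_sums,
    read_cohort,
    truncate_outliers,
    validate_costs,
    validate_participants,
    write_cohort,
)
from mbrcea.exceptions import (
    CohortValidationError,
    ConfigError,
    DataCompletenessError,
    ReferentialError,
    SchemaError,
)

from conftest import flat_panel, make_participant, make_records


def three_person_cohort():
    records = make_records([
        make_participant("A", arm="MBR"),
        make_participant("B", arm="control", sex="female", gcps_grade="III"),
        make_participant("C", arm="control", gcps_grade="IV"),
    ])
    panels = flat_panel(["A", "B", "C"])
    return records, panels


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        records, panels = three_person_cohort()
        pp, pc = tmp_path / "p.csv", tmp_path / "c.csv"
        write_cohort(records, panels, pp, pc)
        r2, c2 = read_cohort(pp, pc)
        assert len(r2) == 3 and len(c2) == 72
        pd.testing.assert_frame_equal(validate_participants(records), r2)
        pd.testing.assert_frame_equal(
            validate_costs(panels), c2, check_dtype=False
        )

    def test_unknown_gcps_grade_rejected(self):
        records, _ = three_person_cohort()
        records.loc[1, "gcps_grade"] = "V"
        with pytest.raises(CohortValidationError, match="gcps_grade"):
            validate_participants(records)

    def test_missing_column_named(self):
        records, _ = three_person_cohort()
        with pytest.raises(SchemaError, match="eq5d_baseline"):
            validate_participants(records.drop(columns=["eq5d_baseline"]))

    def test_cost_partition_invariant(self):
        _, panels = three_person_cohort()
        panels.loc[3, "bp_inpatient_cost"] += 5.0
        with pytest.raises(CohortValidationError, match="inpatient"):
            validate_costs(panels)

    def test_unknown_participant_in_costs(self):
        records, panels = three_person_cohort()
        panels.loc[0, "participant_id"] = "GHOST"
        with pytest.raises(ReferentialError, match="GHOST"):
            validate_costs(panels, known_ids=records["participant_id"])

    @pytest.mark.parametrize("column,value", [
        ("sick_days_baseline", 184),
        ("eq5d_followup", 1.2),
        ("arm", "placebo"),
        ("cci_class", "6"),
    ])
    def test_out_of_range_values_rejected(self, column, value):
        records, _ = three_person_cohort()
        records.loc[0, column] = value
        with pytest.raises(CohortValidationError):
            validate_participants(records)

    def test_duplicate_participant_rejected(self):
        records, _ = three_person_cohort()
        records.loc[2, "participant_id"] = "A"
        with pytest.raises(CohortValidationError, match="duplicate"):
            validate_participants(records)


class TestExclusions:
    def test_single_rule_counts(self):
        rows = [make_participant(f"P{i}") for i in range(8)]
        rows += [make_participant("Q1", invoice_years_with_billing=2),
                 make_participant("Q2", invoice_years_with_billing=0)]
        records = make_records(rows)
        out, audit = apply_exclusions(records, ["no_billing_year"])
        assert len(out) == 8
        assert [(s.step, s.n_overall) for s in audit.steps] == [
            ("initial", 10), ("no_billing_year", 8)]

    def test_empty_rule_list_is_identity(self):
        records, _ = three_person_cohort()
        out, audit = apply_exclusions(records, [])
        pd.testing.assert_frame_equal(out, records)
        assert len(audit.steps) == 1 and audit.steps[0].step == "initial"

    def test_unknown_rule_rejected(self):
        records, _ = three_person_cohort()
        with pytest.raises(ConfigError, match="mystery"):
            apply_exclusions(records, ["mystery"])

    def test_full_cascade_on_seeded_flags(self):
        # 40 participants; 3 SUTVA, 5 deductible-only, 4 non-exercising,
        # no overlapping flags -> 28 survive all four rules
        rows = []
        for i in range(40):
            over = {}
            if i < 3:
                over["sutva_violation"] = True
            elif i < 8:
                over["deductible_only"] = True
            elif i < 12:
                over["completed_exercise"] = False
            rows.append(make_participant(f"P{i:02d}", **over))
        records = make_records(rows)
        rules = ["no_billing_year", "sutva", "deductible", "non_exercising"]
        out, audit = apply_exclusions(records, rules)
        # independent brute-force count over the flags
        expected = sum(
            1 for r in rows
            if r["invoice_years_with_billing"] == 4
            and not r["sutva_violation"] and not r["deductible_only"]
            and r["completed_exercise"]
        )
        assert len(out) == expected == 28
        # order-sensitive but count-conserving: removed + retained = input
        for prev, step in zip(audit.steps, audit.steps[1:]):
            assert step.n_overall + step.n_removed == prev.n_overall

    def test_filtering_is_stable(self):
        rows = [make_participant(f"P{i}", sutva_violation=(i == 2))
                for i in range(5)]
        out, _ = apply_exclusions(make_records(rows), ["sutva"])
        assert list(out["participant_id"]) == ["P0", "P1", "P3", "P4"]


class TestTruncation:
    def test_threshold_is_inclusive(self):
        records = make_records([make_participant("A"), make_participant("B")])
        # A: pre-index bp exactly 1750 * 8 = 14,000 -> removed ("at least")
        panels = pd.concat([
            flat_panel(["A"], total=3000.0, bp=1750.0),
            flat_panel(["B"], total=3000.0, bp=100.0),
        ])
        out, step = truncate_outliers(records, panels, 14_000.0)
        assert list(out["participant_id"]) == ["B"]
        assert step.n_removed == 1

    def test_identity_below_threshold(self):
        records, panels = three_person_cohort()
        out, step = truncate_outliers(records, panels, 14_000.0)
        assert len(out) == 3 and step.n_removed == 0

    def test_seeded_outlier_counts(self):
        rows = [make_participant(f"P{i:02d}") for i in range(20)]
        records = make_records(rows)
        heavy = {"P03", "P07", "P11", "P19"}
        frames = [
            flat_panel([pid], total=6000.0, bp=2000.0) if pid in heavy
            else flat_panel([pid], total=500.0, bp=200.0)
            for pid in records["participant_id"]
        ]
        panels = pd.concat(frames, ignore_index=True)
        # brute-force per-participant baseline sums as the oracle
        pre = panels[panels.quarter_offset.between(-8, -1)]
        oracle = pre.groupby("participant_id")["bp_cost"].sum()
        assert set(oracle.index[oracle >= 14_000]) == heavy
        out, step = truncate_outliers(records, panels, 14_000.0)
        assert len(out) == 16 and step.n_removed == 4

    def test_missing_pretreatment_quarters(self):
        records = make_records([make_participant("A")])
        panels = flat_panel(["A"], quarters=range(-4, 8))
        with pytest.raises(DataCompletenessError):
            truncate_outliers(records, panels, 14_000.0)


class TestAggregation:
    def test_zero_rate_is_plain_sum(self):
        panels = flat_panel(["A"], total=100.0, bp=50.0)
        agg = aggregate_periods(panels, "total", 0.0)
        row = agg.iloc[0]
        assert row["baseline_sum"] == pytest.approx(800.0)
        assert row["followup_sum"] == pytest.approx(800.0)

    def test_closed_form_discounting(self):
        # €250/quarter in follow-up: €1000 per year ->
        # 1000/1.03 + 1000/1.03^2 = 1913.47
        panels = flat_panel(
            ["A"], total=lambda q: 250.0 if q >= 0 else 0.0, bp=0.0
        )
        agg = aggregate_periods(panels, "total", 0.03)
        assert agg.iloc[0]["followup_sum"] == pytest.approx(
            1000 / 1.03 + 1000 / 1.03**2, abs=1e-9
        )
        assert agg.iloc[0]["baseline_sum"] == 0.0

    def test_discounting_monotone_in_rate(self, small_cohort):
        _, panels, _ = small_cohort
        a3 = aggregate_periods(panels, "bp", 0.03).set_index("participant_id")
        a5 = aggregate_periods(panels, "bp", 0.05).set_index("participant_id")
        a0 = aggregate_periods(panels, "bp", 0.0).set_index("participant_id")
        assert (a5["followup_sum"] < a3["followup_sum"]).all()
        assert (a3["followup_sum"] < a0["followup_sum"]).all()
        pd.testing.assert_series_equal(a3["baseline_sum"], a0["baseline_sum"])

    def test_unknown_outcome_rejected(self):
        panels = flat_panel(["A"])
        with pytest.raises(ConfigError):
            aggregate_periods(panels, "dental", 0.0)


class TestCurrencyAdjustment:
    def test_ratio_scaling(self):
        panels = flat_panel(["A"], total=200.0, bp=100.0)
        panels["calendar_year"] = 2015
        out = adjust_to_reference_euros(panels, {2015: 100, 2020: 110}, 2020)
        assert np.allclose(out["total_cost"], 220.0)
        assert np.allclose(out["bp_cost"], 110.0)

    def test_absent_table_is_identity(self):
        panels = flat_panel(["A"])
        out = adjust_to_reference_euros(panels, None, 2020)
        pd.testing.assert_frame_equal(out, panels)

    def test_flat_index_is_identity(self):
        panels = flat_panel(["A"])
        panels["calendar_year"] = 2016
        out = adjust_to_reference_euros(panels, {2016: 104, 2020: 104}, 2020)
        assert np.allclose(out["total_cost"], panels["total_cost"])

    def test_missing_year_rejected(self):
        panels = flat_panel(["A"])
        panels["calendar_year"] = 2013
        with pytest.raises(ConfigError, match="2013"):
            adjust_to_reference_euros(panels, {2020: 110}, 2020)


def test_pretreatment_sums_brute_force(small_cohort):
    _, panels, _ = small_cohort
    sums = pretreatment_sums(panels, "bp")
    pid = sums.index[5]
    manual = panels[(panels.participant_id == pid)
                    & panels.quarter_offset.between(-8, -1)]["bp_cost"].sum()
    assert sums[pid] == pytest.approx(manual)
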