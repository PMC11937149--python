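"""Cost construction: intervention allocation, ceiling-rule medication
costing, total assembly, and the additivity/monotonicity contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trialcea as tc
from trialcea.costing import MedChangeLine, cost_dataset, medication_cost, total_cost
from trialcea.synthetic import SERVICE_ITEMS


class TestInterventionAllocation:
    def test_implementation_cost_spread_over_participants(self):
        # €53,492 of fixed+variable outlays over 208 participants -> €257
        spec = tc.InterventionCostSpec(30_000.0, 23_492.0, 208)
        assert round(tc.allocate_intervention_cost(spec)) == 257

    def test_zero_totals(self):
        assert tc.allocate_intervention_cost(
            tc.InterventionCostSpec(0, 0, 10)) == 0.0

    def test_unrounded_value_carried(self):
        spec = tc.InterventionCostSpec(100.0, 50.0, 3)
        assert tc.allocate_intervention_cost(spec) == pytest.approx(50.0)

    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError):
            tc.InterventionCostSpec(100.0, 0.0, 0)


class TestMedicationCosting:
    def test_empty_lines(self):
        assert medication_cost([], 182) == (0.0, 0.0)

    def test_ceiling_dispensings(self):
        # 182 days at a 28-day interval -> 7 dispensings of (30 + 5)
        line = MedChangeLine(1, "started", 30.0, 28)
        started, stopped = medication_cost([line], 182, dispensing_fee=5.0)
        assert started == pytest.approx(7 * 35.0)
        assert stopped == 0.0

    def test_direction_symmetry(self):
        a = MedChangeLine(1, "started", 12.5, 30)
        b = MedChangeLine(1, "stopped", 12.5, 30)
        started, stopped = medication_cost([a, b], 182, dispensing_fee=5.0)
        assert started == stopped

    def test_excluded_line_contributes_nothing(self):
        line = MedChangeLine(1, "started", 30.0, 28, included=False)
        assert medication_cost([line], 182) == (0.0, 0.0)

    def test_nonpositive_interval_names_line(self):
        with pytest.raises(ValueError, match="participant 7"):
            MedChangeLine(7, "started", 30.0, 0)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            medication_cost([], 0)

    @given(cost=st.floats(0, 500), interval=st.integers(1, 365),
           horizon=st.integers(1, 365))
    @settings(max_examples=50, deadline=None)
    def test_dispensing_count_is_ceiling(self, cost, interval, horizon):
        line = MedChangeLine(0, "started", cost, interval)
        started, _ = medication_cost([line], horizon, dispensing_fee=0.0)
        assert started == pytest.approx(math.ceil(horizon / interval) * cost)


def _zero_record(arm="control"):
    rec = {"participant_id": 0, "arm": arm}
    for item in SERVICE_ITEMS:
        rec[f"{item}_baseline"] = 0
        rec[f"{item}_followup"] = 0
    return rec


class TestTotalCost:
    def test_all_zero_control_participant(self):
        bd = total_cost(_zero_record(), tc.default_unit_costs(), None)
        assert bd.total == 0.0

    def test_intervention_only_component(self):
        spec = tc.InterventionCostSpec(100.0, 50.0, 3)
        bd = total_cost(_zero_record("intervention"), tc.default_unit_costs(),
                        spec, period="followup")
        assert bd.total == pytest.approx(50.0)

    def test_baseline_never_includes_intervention_or_medications(self):
        spec = tc.InterventionCostSpec(100.0, 50.0, 3)
        lines = [MedChangeLine(0, "started", 30.0, 28)]
        bd = total_cost(_zero_record("intervention"), tc.default_unit_costs(),
                        spec, period="baseline", med_lines=lines)
        assert bd.total == 0.0

    def test_stopped_medications_can_make_total_negative(self):
        rec = _zero_record()
        rec["gp_surgery_followup"] = 1  # €53 of care
        lines = [MedChangeLine(0, "stopped", 40.0, 28)]  # 7 x €45 saved
        bd = total_cost(rec, tc.default_unit_costs(), None, med_lines=lines)
        assert bd.total < 0
        assert bd.total == pytest.approx(53.0 - 7 * 45.0)

    def test_breakdown_identity(self):
        rec = _zero_record("intervention")
        rec["outpatient_followup"] = 2
        spec = tc.InterventionCostSpec(90.0, 0.0, 3)
        lines = [MedChangeLine(0, "started", 10.0, 91),
                 MedChangeLine(0, "stopped", 20.0, 91)]
        bd = total_cost(rec, tc.default_unit_costs(), spec, med_lines=lines)
        assert bd.total == pytest.approx(bd.intervention_cost + bd.cost_started
                                         - bd.cost_stopped
                                         + sum(bd.service_costs.values()))

    def test_unpriced_item_fails_by_name(self):
        units = tc.UnitCostTable({"gp_surgery": 53.0})
        with pytest.raises(KeyError, match="gp_phone"):
            total_cost(_zero_record(), units, None)

    def test_missing_count_propagates_to_total(self):
        rec = _zero_record()
        rec["ed_visits_followup"] = np.nan
        bd = total_cost(rec, tc.default_unit_costs(), None)
        assert np.isnan(bd.total)


class TestCostDataset:
    def test_matches_per_record_construction(self, small_complete_trial):
        iv = tc.InterventionCostSpec(1000.0, 500.0, 25)
        units = tc.default_unit_costs()
        table = cost_dataset(small_complete_trial, units, iv)
        med = small_complete_trial.med_changes
        for i in range(0, len(table), 7):
            row = small_complete_trial.participants.iloc[i]
            lines = [MedChangeLine(int(r.participant_id), r.direction,
                                   r.ingredient_cost_per_interval,
                                   int(r.dispensing_interval), bool(r.included))
                     for r in med[med["participant_id"]
                                  == row["participant_id"]].itertuples()]
            bd = total_cost(row, units, iv, med_lines=lines)
            assert table.iloc[i]["total_cost_followup"] == pytest.approx(bd.total)

    def test_additivity_of_components(self, small_complete_trial):
        units = tc.default_unit_costs()
        table = cost_dataset(small_complete_trial, units, None)
        service = sum(table[f"cost_{it}_followup"] for it in SERVICE_ITEMS)
        recon = (service + table["intervention_cost"] + table["cost_started"]
                 - table["cost_stopped"])
        pd.testing.assert_series_equal(recon, table["total_cost_followup"],
                                       check_names=False)

    def test_monotonicity_in_counts_and_unit_costs(self, small_complete_trial):
        units = tc.default_unit_costs()
        base = cost_dataset(small_complete_trial, units, None)
        bumped_data = tc.TrialDataset(
            participants=small_complete_trial.participants.assign(
                outpatient_followup=lambda d: d["outpatient_followup"] + 1),
            med_changes=small_complete_trial.med_changes)
        bumped = cost_dataset(bumped_data, units, None)
        assert (bumped["total_cost_followup"]
                >= base["total_cost_followup"]).all()
        pricier = cost_dataset(small_complete_trial, units.scaled(1.15), None)
        assert (pricier["service_cost_followup"]
                >= base["service_cost_followup"]).all()

    def test_unknown_component_rejected_before_compute(self, small_complete_trial):
        with pytest.raises(ValueError, match="unknown cost components"):
            cost_dataset(small_complete_trial, tc.default_unit_costs(), None,
                         exclude_components=("helicopter",))

    def test_hospitalisation_alias_zeroes_inpatient(self, small_complete_trial):
        units = tc.default_unit_costs()
        out = cost_dataset(small_complete_trial, units, None,
                           exclude_components=("hospitalisation",))
        assert (out["cost_inpatient_nights_followup"] == 0).all()


def test_unit_cost_table_round_trip(tmp_path):
    units = tc.default_unit_costs()
    path = tmp_path / "units.csv"
    units.to_csv(path)
    back = tc.UnitCostTable.from_csv(path, dispensing_fee=units.dispensing_fee)
    assert back.costs == units.costs


def test_negative_unit_cost_rejected():
    with pytest.raises(ValueError):
        tc.UnitCostTable({"gp_surgery": -1.0})
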