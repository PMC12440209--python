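"""Patient-log data model: grid alignment, CSV round trip, segmentation."""

import numpy as np
import pandas as pd
import pytest

from glycloop.core_io import (
    BolusEvent, GlucoseTrace, MealEvent, PatientRecord, TherapyParams,
    align_to_grid, load_patient_records, save_patient_records,
    segment_meal_windows, PRE_SAMPLES, POST_SAMPLES,
)
from glycloop.errors import LoadError

from conftest import T0, constant_trace, make_trace


class TestAlignToGrid:
    def test_already_gridded_is_identity(self):
        times = pd.date_range(T0, periods=20, freq="5min")
        vals = np.linspace(100, 150, 20)
        tr = align_to_grid(list(zip(times, vals)))
        assert len(tr) == 20
        np.testing.assert_allclose(tr.values, vals)
        assert not tr.missing.any()

    def test_single_missing_slot_linearly_filled(self):
        times = [T0, T0 + pd.Timedelta(minutes=10)]
        tr = align_to_grid(list(zip(times, [100.0, 110.0])))
        assert len(tr) == 3
        assert tr.values[1] == pytest.approx(105.0)
        assert not tr.missing[1]

    def test_long_gap_stays_missing(self):
        times = [T0, T0 + pd.Timedelta(minutes=30)]
        tr = align_to_grid(list(zip(times, [100.0, 110.0])))
        assert tr.missing[1:-1].all()
        assert np.isnan(tr.values[1:-1]).all()

    def test_duplicate_slot_keeps_last(self, caplog):
        times = [T0, T0 + pd.Timedelta(minutes=1), T0 + pd.Timedelta(minutes=5)]
        tr = align_to_grid(list(zip(times, [100.0, 200.0, 110.0])))
        assert tr.values[0] == 200.0

    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(LoadError):
            align_to_grid([(T0, 100.0), (T0, 110.0)])

    def test_idempotent_on_own_output(self):
        times = [T0 + pd.Timedelta(minutes=m) for m in (0, 5, 10, 40, 45)]
        tr = align_to_grid(list(zip(times, [100.0, 105, 110, 140, 145])))
        again = align_to_grid(
            [(t, v) for t, v, m in zip(tr.times, tr.values, tr.missing) if not m])
        np.testing.assert_array_equal(tr.missing, again.missing)
        np.testing.assert_allclose(tr.values[~tr.missing],
                                   again.values[~again.missing])


class TestCsvRoundTrip:
    def test_well_formed_day_loads_288_samples(self, tmp_path, day_record):
        path = tmp_path / "rec.csv"
        save_patient_records([day_record], path)
        recs = load_patient_records(path)
        assert len(recs) == 1
        assert len(recs[0].trace) == 288

    def test_round_trip_identity(self, tmp_path, day_record):
        path = tmp_path / "rec.csv"
        save_patient_records([day_record], path)
        rec = load_patient_records(path)[0]
        np.testing.assert_array_equal(rec.trace.values, day_record.trace.values)
        np.testing.assert_array_equal(rec.trace.missing, day_record.trace.missing)
        assert rec.trace.start_time == day_record.trace.start_time
        assert [m.time for m in rec.meals] == [m.time for m in day_record.meals]
        assert [m.cho_announced for m in rec.meals] == [60.0]
        assert [b.units for b in rec.boluses] == [6.0]
        assert rec.therapy == day_record.therapy

    def test_round_trip_preserves_actual_carbs(self, tmp_path, day_record):
        day_record.meals[0].cho_actual = 72.0
        path = tmp_path / "rec.csv"
        save_patient_records([day_record], path)
        rec = load_patient_records(path)[0]
        assert rec.meals[0].cho_actual == 72.0
        assert rec.meals[0].cho_announced == 60.0

    def test_out_of_range_glucose_flagged_missing(self, tmp_path):
        rows = "patient_id,timestamp,cgm_mg_dl,cho_g,bolus_u\n" + "\n".join(
            f"p1,{(T0 + pd.Timedelta(minutes=5 * i)).isoformat()},"
            f"{900.0 if i == 2 else 100.0},," for i in range(5))
        path = tmp_path / "bad.csv"
        path.write_text(rows + "\n")
        rec = load_patient_records(path)[0]
        assert rec.trace.missing[2]
        assert not rec.trace.missing[[0, 1, 3, 4]].any()

    def test_unparseable_timestamp_raises_load_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,timestamp,cgm_mg_dl,cho_g,bolus_u\n"
                        "p1,not-a-time,100,,\n")
        with pytest.raises(LoadError, match="bad.csv"):
            load_patient_records(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("patient_id,timestamp,cgm_mg_dl,cho_g,bolus_u\n")
        with pytest.raises(LoadError):
            load_patient_records(path)


class TestSegmentation:
    def test_complete_window_sizes(self, day_record):
        windows = segment_meal_windows(day_record)
        assert len(windows) == 1
        assert len(windows[0].pre) == PRE_SAMPLES
        assert len(windows[0].post) == POST_SAMPLES
        # pre window ends exactly at meal onset
        assert windows[0].pre.times[-1] == day_record.meals[0].time

    def test_meal_too_early_dropped(self, therapy):
        trace = constant_trace(120.0, 288)
        rec = PatientRecord(
            patient_id="p", trace=trace,
            meals=[MealEvent(time=T0 + pd.Timedelta(hours=2), cho_announced=40.0)],
            boluses=[], therapy=therapy)
        assert segment_meal_windows(rec) == []

    def test_bolus_sum_within_quarter_hour(self, therapy):
        noon = T0 + pd.Timedelta(hours=12)
        rec = PatientRecord(
            patient_id="p", trace=constant_trace(120.0, 288),
            meals=[MealEvent(time=noon, cho_announced=40.0)],
            boluses=[
                BolusEvent(time=noon - pd.Timedelta(minutes=5), units=2.0),
                BolusEvent(time=noon + pd.Timedelta(minutes=10), units=1.0),
                BolusEvent(time=noon + pd.Timedelta(minutes=40), units=5.0),
            ],
            therapy=therapy)
        (w,) = segment_meal_windows(rec)
        assert w.bolus_units == pytest.approx(3.0)

    def test_sparse_window_dropped(self, therapy):
        vals = np.full(288, 120.0)
        missing = np.zeros(288, dtype=bool)
        missing[120:140] = True  # 20 missing slots in the pre window
        rec = PatientRecord(
            patient_id="p", trace=make_trace(vals, missing=missing),
            meals=[MealEvent(time=T0 + pd.Timedelta(hours=12), cho_announced=40.0)],
            boluses=[], therapy=therapy)
        assert segment_meal_windows(rec) == []

    def test_window_count_bounded_by_meals(self, therapy):
        meals = [MealEvent(time=T0 + pd.Timedelta(hours=h), cho_announced=50.0)
                 for h in (2, 8, 13, 19, 23)]
        rec = PatientRecord(patient_id="p", trace=constant_trace(120.0, 288),
                            meals=meals, boluses=[], therapy=therapy)
        windows = segment_meal_windows(rec)
        assert len(windows) <= len(meals)
        assert len(windows) == 3  # 02:00 lacks pre history, 23:00 lacks post


class TestValidation:
    def test_therapy_bounds(self):
        with pytest.raises(ValueError):
            TherapyParams(cr=-1.0, cf=30.0)
        with pytest.raises(ValueError):
            TherapyParams(cr=10.0, cf=30.0, cgm_target=300.0)

    def test_negative_carbs_rejected(self):
        with pytest.raises(ValueError):
            MealEvent(time=T0, cho_announced=-5.0)
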