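"""Error metrics, AAMI/BHS standards, aggregation, sweeps, latency."""

import time

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cuffmap.evaluate import (
    CumulativePcts,
    aami_check,
    aggregate_per_patient,
    bhs_grade,
    calibration_sweep,
    compute_errors,
    cumulative_error_pct,
    latency_benchmark,
    standards_verdict,
)
from cuffmap.mechanistic import carry_forward_track
from cuffmap.simulate import SimParams, generate_record


class TestComputeErrors:
    def test_perfect_predictions(self):
        ref = np.array([80.0, 85.0, 90.0])
        s = compute_errors(ref, ref)
        assert (s.me, s.mae, s.sd_error) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        ref = np.array([80.0, 85.0, 90.0])
        s = compute_errors(ref + 3.0, ref)
        assert (s.me, s.mae, s.sd_error) == (3.0, 3.0, 0.0)

    def test_symmetric_errors_use_population_sd(self):
        s = compute_errors(np.array([82.0, 78.0]), np.array([80.0, 80.0]))
        assert (s.me, s.mae) == (0.0, 2.0)
        assert s.sd_error == 2.0  # population (ddof=0) convention

    def test_shift_invariance_of_sd(self):
        rng = np.random.default_rng(0)
        ref = 80 + 5 * rng.normal(size=100)
        pred = ref + rng.normal(size=100)
        a = compute_errors(pred, ref)
        b = compute_errors(pred + 4.0, ref)
        assert b.me == pytest.approx(a.me + 4.0)
        assert b.sd_error == pytest.approx(a.sd_error)
        assert a.mae >= abs(a.me)

    def test_masks_respected(self):
        pred = np.array([80.0, 999.0, 82.0])
        ref = np.array([80.0, 80.0, 80.0])
        s = compute_errors(pred, ref, missing=np.array([False, True, False]))
        assert s.mae == 1.0 and s.n_samples == 2

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            compute_errors(np.array([np.nan]), np.array([80.0]))


class TestCumulative:
    def test_hand_counted_example(self):
        pcts = cumulative_error_pct(np.array([1.0, 4.0, 6.0, 12.0, 20.0]))
        assert pcts.as_tuple() == (40.0, 60.0, 80.0)

    def test_all_zero_errors(self):
        assert cumulative_error_pct(np.zeros(10)).as_tuple() == (100.0, 100.0, 100.0)

    def test_all_large_errors(self):
        assert cumulative_error_pct(np.full(10, 50.0)).as_tuple() == (0.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_error_pct(np.array([]))


class TestBhs:
    @pytest.mark.parametrize(
        "pcts, grade",
        [
            ((65.7, 88.3, 96.1), "A"),
            ((57.7, 83.5, 93.4), "B"),
            ((40.8, 70.1, 86.3), "C"),
            ((31.8, 59.2, 79.4), "below_C"),
            ((60.0, 85.0, 95.0), "A"),  # inclusive boundary
            ((72.1, 91.2, 95.3), "A"),
        ],
    )
    def test_published_report_rows(self, pcts, grade):
        assert bhs_grade(CumulativePcts(*pcts)) == grade

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(0, 100) for _ in range(3)]),
           st.floats(0, 30), st.integers(0, 2))
    def test_raising_a_pct_never_lowers_grade(self, pcts, bump, idx):
        order = {"below_C": 0, "C": 1, "B": 2, "A": 3}
        base = tuple(sorted(pcts))
        raised = list(base)
        raised[idx] = min(100.0, raised[idx] + bump)
        raised = tuple(sorted(raised))
        assert order[bhs_grade(CumulativePcts(*raised))] >= order[bhs_grade(CumulativePcts(*base))]


class TestAami:
    def test_published_pass_row(self):
        s = compute_errors(np.array([80.3]), np.array([80.0]))
        s = type(s)(me=0.3, mae=4.6, sd_error=6.3, mae_sd=4.7, n_samples=1000)
        ok, me_ok, sd_ok, n_ok = aami_check(s, 284)
        assert ok and me_ok and sd_ok and n_ok

    def test_me_boundary_fails_above_five(self):
        s = compute_errors(np.array([85.1, 85.1]), np.array([80.0, 80.0]))
        ok, me_ok, sd_ok, n_ok = aami_check(s, 100)
        assert not ok and not me_ok and sd_ok and n_ok

    def test_inclusive_bounds(self):
        s = type(compute_errors(np.array([1.0]), np.array([1.0])))(
            me=0.0, mae=6.0, sd_error=8.0, mae_sd=1.0, n_samples=10)
        ok, *_ = aami_check(s, 85)
        assert ok

    def test_verdict_combines_both_standards(self):
        s = type(compute_errors(np.array([1.0]), np.array([1.0])))(
            me=0.3, mae=4.6, sd_error=6.3, mae_sd=4.7, n_samples=10)
        v = standards_verdict(s, CumulativePcts(65.7, 88.3, 96.1), 284)
        assert v.aami_pass and v.bhs_grade == "A"


class TestAggregate:
    def test_single_patient_equals_its_summary(self):
        table = pd.DataFrame({"patient_id": "p0", "error": [1.0, -1.0, 2.0]})
        agg = aggregate_per_patient(table)
        assert len(agg) == 2  # patient row + study row
        assert agg.iloc[0]["mae"] == pytest.approx(4.0 / 3.0)
        assert agg.iloc[-1]["mae"] == pytest.approx(agg.iloc[0]["mae"])

    def test_study_mae_is_patient_mean(self):
        table = pd.DataFrame(
            {"patient_id": ["a"] * 2 + ["b"] * 4, "error": [2.0, -2.0, 4.0, -4.0, 4.0, 4.0]}
        )
        agg = aggregate_per_patient(table)
        assert agg.iloc[-1]["mae"] == pytest.approx((2.0 + 4.0) / 2)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"patient_id": rng.choice(["a", "b", "c"], 60), "error": rng.normal(size=60)}
        )
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            aggregate_per_patient(table), aggregate_per_patient(shuffled)
        )

    def test_empty_patient_excluded(self):
        table = pd.DataFrame(
            {"patient_id": ["a", "a", "b"], "error": [1.0, 2.0, np.nan]}
        )
        agg = aggregate_per_patient(table)
        assert list(agg["patient_id"]) == ["a", "study"]


class TestSweep:
    def test_perfect_predictor_zero_mae_everywhere(self):
        records = {
            iv: [generate_record(SimParams(seed=s, cuff_interval_s=iv, cuff_noise_sigma=0.0))[0]
                 for s in range(2)]
            for iv in (180, 300, 600)
        }

        def oracle(record):
            return record.map_ref.values, record.map_ref.missing.copy()

        table = calibration_sweep(lambda iv: oracle, lambda iv: records[iv])
        assert list(table["interval_s"]) == [180, 300, 600]
        assert np.allclose(table["mae"], 0.0)
        assert list(table["bhs_grade"]) == ["A", "A", "A"]

    def test_carry_forward_degrades_with_interval(self):
        def record_factory(iv):
            return [generate_record(SimParams(seed=s, cuff_interval_s=iv))[0]
                    for s in range(8)]

        table = calibration_sweep(lambda iv: carry_forward_track, record_factory)
        maes = list(table["mae"])
        assert maes[0] < maes[1] < maes[2]


class TestLatency:
    def test_sleep_stub_measured_within_tolerance(self):
        batches = [[np.zeros(10)] for _ in range(15)]
        report = latency_benchmark(lambda b: time.sleep(0.005), batches)
        assert report.n_batches == 15
        assert report.mean_batch_ms == pytest.approx(5.0, rel=0.5)
        assert report.mean_per_sample_ms == pytest.approx(report.mean_batch_ms / 10, rel=1e-6)

    def test_too_few_batches_rejected(self):
        with pytest.raises(ValueError):
            latency_benchmark(lambda b: None, [[np.zeros(2)]] * 5)
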