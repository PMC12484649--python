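"""Synthetic-physiology generator: determinism, coupling, morphology."""

import numpy as np
import pytest

from cuffmap.mechanistic import MechanisticParams, mechanistic_predict
from cuffmap.pulses import detect_pulses
from cuffmap.records import record_equal
from cuffmap.segments import compute_quality_metrics, segment_record
from cuffmap.simulate import (
    DEFAULT_MECH_PARAMS,
    ArtifactSpec,
    SimParams,
    generate_record,
    inject_artifacts,
    simulate_latent_features,
    simulate_map_trajectory,
    synthesize_cuff,
    synthesize_waveforms,
)


class TestMapTrajectory:
    def test_zero_noise_is_constant_baseline(self):
        params = SimParams(map_volatility=0.0, episode_rate=0.0, map_baseline=80.0)
        series = simulate_map_trajectory(params, seed=3)
        assert series.shape == (3600,)
        np.testing.assert_allclose(series, 80.0)

    def test_same_seed_bitwise_identical(self):
        params = SimParams()
        a = simulate_map_trajectory(params, seed=5)
        b = simulate_map_trajectory(params, seed=5)
        assert np.array_equal(a, b)
        c = simulate_map_trajectory(params, seed=6)
        assert not np.array_equal(a, c)

    def test_long_run_mean_near_baseline(self):
        # Monte-Carlo: stationary mean reverts to the baseline
        means, sds = [], []
        for seed in range(20):
            series = simulate_map_trajectory(SimParams(duration_s=10_000), seed=seed)
            means.append(series.mean())
            sds.append(series.std())
        assert abs(np.mean(means) - 80.0) < 5.0
        assert min(sds) > 0.0

    def test_range_clipped(self):
        series = simulate_map_trajectory(SimParams(episode_depth=60.0), seed=9)
        assert series.min() >= 40.0 and series.max() <= 160.0


class TestLatentFeatures:
    def test_exact_inversion_when_noise_free(self):
        map_1hz = simulate_map_trajectory(SimParams(), seed=2)
        feats = simulate_latent_features(map_1hz, DEFAULT_MECH_PARAMS, 0.0, seed=3)
        pred, _ = mechanistic_predict(feats.hr, feats.pi, feats.nra, DEFAULT_MECH_PARAMS)
        assert np.max(np.abs(pred - feats.map_consistent)) <= 1e-9

    def test_feature_bounds(self):
        map_1hz = simulate_map_trajectory(SimParams(), seed=2)
        feats = simulate_latent_features(map_1hz, DEFAULT_MECH_PARAMS, 1.0, seed=3)
        assert feats.hr.min() >= 40 and feats.hr.max() <= 140
        assert feats.pi.min() > 0.1 and feats.pi.max() <= 20
        assert feats.nra.min() > 0 and feats.nra.max() <= 1

    def test_degenerate_alpha_rejected(self):
        map_1hz = np.full(3600, 80.0)
        with pytest.raises(ValueError, match="alpha"):
            simulate_latent_features(map_1hz, MechanisticParams(-1.0, 0.2, 0.1, 20.0), 0.0, 1)

    def test_residual_sd_matches_noise_level(self):
        # the induced MAP residual should have sd ~ feature_noise_sd = 1
        resid = []
        for seed in range(20):
            map_1hz = simulate_map_trajectory(SimParams(), seed=seed)
            feats = simulate_latent_features(map_1hz, DEFAULT_MECH_PARAMS, 1.0, seed=seed + 50)
            pred, _ = mechanistic_predict(feats.hr, feats.pi, feats.nra, DEFAULT_MECH_PARAMS)
            resid.append(pred - feats.map_consistent)
        sd = np.concatenate(resid).std()
        assert 0.8 <= sd <= 1.2


class TestWaveforms:
    def test_r_spike_interval_matches_heart_rate(self):
        n = 60
        hr = np.full(n, 75.0)
        ppg, ecg, beats = synthesize_waveforms(hr, np.full(n, 3.0), np.full(n, 0.4), seed=1)
        spikes = np.flatnonzero(ecg > 0.5)
        gaps = np.diff(spikes)
        assert np.all(np.abs(gaps - 100) <= 1)  # 0.8 s at 125 Hz

    def test_pi_encoded_within_tolerance(self):
        n = 30
        ppg, _, beats = synthesize_waveforms(
            np.full(n, 75.0), np.full(n, 5.0), np.full(n, 0.4), seed=1
        )
        # measure a mid-record beat directly on the template
        i0, i1 = int(beats[10] * 125), int(beats[11] * 125)
        beat = ppg[i0:i1]
        measured = 100 * (beat.max() - beat.min()) / beat.mean()
        assert abs(measured - 5.0) / 5.0 < 0.05

    def test_nra_encoded_within_tolerance(self):
        n = 30
        ppg, _, beats = synthesize_waveforms(
            np.full(n, 75.0), np.full(n, 5.0), np.full(n, 0.4), seed=1
        )
        lm = detect_pulses(ppg)
        nra = (lm.notch_value - lm.foot_value) / (lm.peak_value - lm.foot_value)
        assert np.nanmedian(nra) == pytest.approx(0.40, abs=0.02)

    def test_non_positive_hr_rejected(self):
        hr = np.full(10, 75.0)
        hr[4] = 0.0
        with pytest.raises(ValueError, match="HR"):
            synthesize_waveforms(hr, np.full(10, 3.0), np.full(10, 0.4), seed=1)


class TestCuff:
    def test_zero_sigma_matches_arterial_exactly(self):
        map_1hz = simulate_map_trajectory(SimParams(), seed=4)
        events = synthesize_cuff(map_1hz, 300, mu=0.0, sigma=0.0, seed=1)
        for ev in events:
            assert ev.map_mmHg == map_1hz[min(int(ev.time_s), 3599)]

    def test_event_count_includes_start(self):
        map_1hz = np.full(3600, 80.0)
        events = synthesize_cuff(map_1hz, 300, seed=1)
        assert len(events) == 13  # t = 0, 300, ..., 3600
        assert events[0].time_s == 0.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            synthesize_cuff(np.full(3600, 80.0), 0, seed=1)


class TestGenerateRecord:
    def test_below_one_hour_rejected(self):
        with pytest.raises(ValueError, match="one hour"):
            SimParams(duration_s=3599)

    def test_seed_sensitivity(self):
        a, _ = generate_record(SimParams(seed=10))
        b, _ = generate_record(SimParams(seed=11))
        assert not np.array_equal(a.ppg.values, b.ppg.values)

    def test_determinism(self):
        a, _ = generate_record(SimParams(seed=10))
        b, _ = generate_record(SimParams(seed=10))
        assert record_equal(a, b)

    def test_truth_consistent_with_record(self, noise_free_record_truth):
        record, truth = noise_free_record_truth
        pred, _ = mechanistic_predict(
            truth.hr_latent, truth.pi_latent, truth.nra_latent, truth.true_mech_params
        )
        # noise-free: drift off, observed features = latent features
        assert np.max(np.abs(pred - record.map_ref.values)) <= 1e-9

    def test_clean_segments_pass_qc(self, default_record_truth):
        record, _ = default_record_truth
        for segment in segment_record(record):
            assert compute_quality_metrics(segment).overall_pass


class TestInjectArtifacts:
    def test_empty_spec_is_identity(self, default_record_truth):
        record, _ = default_record_truth
        out = inject_artifacts(record, [])
        assert record_equal(record, out)

    def test_untouched_samples_bitwise_unchanged(self, default_record_truth):
        record, _ = default_record_truth
        spec = ArtifactSpec("level_shift", "map_ref", 600.0, 100.0, 20.0)
        out = inject_artifacts(record, spec)
        assert np.array_equal(out.map_ref.values[:600], record.map_ref.values[:600])
        assert np.array_equal(out.map_ref.values[700:], record.map_ref.values[700:])
        assert np.array_equal(out.ppg.values, record.ppg.values)

    def test_window_outside_record_rejected(self, default_record_truth):
        record, _ = default_record_truth
        with pytest.raises(ValueError, match="outside"):
            inject_artifacts(record, ArtifactSpec("flatline", "hr", 3500.0, 200.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ArtifactSpec("dropout", "hr", 0.0, 10.0)

    def test_missing_run_flips_map_missing_criterion(self, default_record_truth):
        record, _ = default_record_truth
        spec = ArtifactSpec("missing_run", "map_ref", 300.0, 90.0)  # 30% of a segment
        seg = [s for s in segment_record(inject_artifacts(record, spec))
               if s.start_s == 300][0]
        report = compute_quality_metrics(seg)
        assert report.rejection_reasons == ["map_missing"]
        assert report.criteria["map_missing"].value == pytest.approx(0.30, abs=0.01)

    def test_flatline_flips_map_sd_criterion(self, default_record_truth):
        record, _ = default_record_truth
        spec = ArtifactSpec("flatline", "map_ref", 300.0, 300.0)
        seg = [s for s in segment_record(inject_artifacts(record, spec))
               if s.start_s == 300][0]
        assert compute_quality_metrics(seg).rejection_reasons == ["map_sd"]
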