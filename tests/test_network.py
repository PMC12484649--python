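"""Architecture contracts: causality, receptive field, calibration state."""

import numpy as np
import pytest

from cuffmap.network import (
    CausalMapNet,
    NetConfig,
    TrainConfig,
    build_network,
    encode_highfreq,
    init_calibration_state,
    load_checkpoint,
    predict_segment,
    recalibrate,
    save_checkpoint,
    split_patients,
    train_model,
)
from cuffmap.segments import segment_record
from cuffmap.simulate import SimParams, generate_record

SMALL = dict(n_conv_layers=3, conv_channels=3, lstm_hidden=8, dropout=0.0)


def _random_inputs(rng, b, t_sec):
    ppg = 1.0 + 0.05 * rng.normal(size=(b, t_sec * 125))
    ecg = 0.3 * rng.normal(size=(b, t_sec * 125))
    feats = np.stack(
        [75 + 5 * rng.normal(size=(b, t_sec)), 3 + 0.5 * rng.normal(size=(b, t_sec)),
         0.5 + 0.1 * rng.normal(size=(b, t_sec))], axis=2)
    cuff = 80 + 10 * rng.normal(size=b)
    return ppg, ecg, feats, cuff


class TestConfig:
    def test_param_count_deterministic_per_config(self):
        cfg = NetConfig(**SMALL)
        a, b = build_network(cfg, seed=0), build_network(cfg, seed=99)
        assert a.param_count == b.param_count
        assert a.config.config_hash() == b.config.config_hash()

    def test_config_hash_distinguishes(self):
        assert NetConfig(**SMALL).config_hash() != NetConfig().config_hash()

    def test_receptive_field_formula(self):
        assert NetConfig(n_conv_layers=8).receptive_field == 3571
        assert NetConfig(n_conv_layers=1).receptive_field == 15

    def test_left_pad_rule(self):
        net = build_network(NetConfig(**SMALL))
        # dilation doubles per layer; pad = (k - 1) * dilation
        assert [c.pad for c in net.convs] == [14, 28, 56]
        net8 = build_network(NetConfig(n_conv_layers=4, conv_channels=2))
        assert net8.convs[3].pad == (15 - 1) * 8 == 112

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(n_conv_layers=0)

    def test_non_unit_stride_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(stride=2)


class TestEncoder:
    def test_five_minute_window_shapes(self):
        net = build_network(NetConfig(**SMALL))
        x = np.ones((1, 37_500))
        emb = encode_highfreq(net, x, np.zeros_like(x))
        assert emb.shape == (1, 3, 300)  # 300 one-second steps

    def test_embedding_causality(self):
        """An impulse at sample s leaves all embedding steps strictly
        before second floor(s/125) bitwise unchanged."""
        rng = np.random.default_rng(0)
        net = build_network(NetConfig(**SMALL), seed=1)
        base_ppg = np.ones((1, 10 * 125))
        ecg = np.zeros_like(base_ppg)
        for s in (250, 624, 1111):
            pert = base_ppg.copy()
            pert[0, s] += 0.5
            a = net.embed_1hz(base_ppg, ecg)
            b = net.embed_1hz(pert, ecg)
            sec = s // 125
            assert np.array_equal(a[:, :, :sec], b[:, :, :sec])
            assert not np.array_equal(a[:, :, sec:], b[:, :, sec:])

    def test_zero_input_constant_embedding(self):
        net = build_network(NetConfig(**SMALL), seed=2)
        cfg = net.config
        # raw inputs equal to the normalization centers -> all-zero
        # normalized input -> bias-only response, constant over time
        ppg = np.full((1, 5 * 125), cfg.ppg_norm[0])
        ecg = np.full((1, 5 * 125), cfg.ecg_norm[0])
        emb = net.embed_1hz(ppg, ecg)
        assert np.allclose(emb, emb[:, :, :1], atol=1e-6)

    def test_trailing_partial_second_dropped(self):
        net = build_network(NetConfig(**SMALL))
        x = np.ones((1, 3 * 125 + 60))
        emb = net.embed_1hz(x, np.zeros_like(x))
        assert emb.shape[-1] == 3


class TestCalibrationState:
    def test_center_cuff_gives_zero_state(self):
        state = init_calibration_state(80.0, NetConfig())
        assert np.all(state.h0 == 0.0) and np.all(state.c0 == 0.0)

    def test_scale_normalization(self):
        state = init_calibration_state(100.0, NetConfig())
        assert np.all(state.h0 == 1.0)

    def test_deterministic(self):
        a = init_calibration_state(93.0, NetConfig())
        b = init_calibration_state(93.0, NetConfig())
        assert np.array_equal(a.h0, b.h0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            init_calibration_state(10.0, NetConfig())

    def test_recalibrate_equals_init(self):
        cfg = NetConfig()
        state = init_calibration_state(70.0, cfg)
        reset = recalibrate(state, 95.0, cfg)
        ref = init_calibration_state(95.0, cfg)
        assert np.array_equal(reset.h0, ref.h0) and reset.cuff_map == 95.0

    def test_recalibration_leaves_weights_untouched(self, default_record_truth):
        record, _ = default_record_truth
        net = build_network(NetConfig(**SMALL), seed=3)
        before = net.weights_hash()
        for seg in segment_record(record)[:2]:
            predict_segment(net, seg)
        assert net.weights_hash() == before


@pytest.fixture(scope="module")
def net_and_segments(default_record_truth):
    record, _ = default_record_truth
    return build_network(NetConfig(**SMALL), seed=4), segment_record(record)


class TestPredictSegment:

    def test_inference_deterministic(self, net_and_segments):
        net, segs = net_and_segments
        a = predict_segment(net, segs[0])
        b = predict_segment(net, segs[0])
        assert np.array_equal(a.values, b.values)

    def test_shape_contract(self):
        """A T-second segment yields exactly T predictions."""
        rng = np.random.default_rng(5)
        net = build_network(NetConfig(**SMALL), seed=5)
        for t_sec in (180, 300, 600):
            ppg, ecg, feats, cuff = _random_inputs(rng, 1, t_sec)
            y = net.forward(ppg, ecg, feats, cuff)
            assert y.shape == (1, t_sec)

    def test_end_to_end_causality(self, net_and_segments):
        """Perturbing the last 10 s leaves the first 290 outputs unchanged."""
        net, segs = net_and_segments
        seg = segs[0]
        ppg = seg.ppg.values[None, :].copy()
        ecg = seg.ecg.values[None, :].copy()
        feats = np.stack([seg.hr.values, seg.pi.values, seg.nra.values], axis=1)[None]
        cuff = np.array([seg.opening_cuff.map_mmHg])
        ya = net.forward(ppg, ecg, feats, cuff)
        ppg2 = ppg.copy()
        ppg2[0, -10 * 125:] += 0.3
        feats2 = feats.copy()
        feats2[0, -10:, :] *= 1.1
        yb = net.forward(ppg2, ecg, feats2, cuff)
        assert np.array_equal(ya[0, :290], yb[0, :290])
        assert not np.array_equal(ya[0, 290:], yb[0, 290:])

    def test_provenance(self, net_and_segments):
        net, segs = net_and_segments
        pred = predict_segment(net, segs[1])
        assert pred.config_hash == net.config.config_hash()
        assert pred.opening_cuff == segs[1].opening_cuff.map_mmHg
        assert pred.values.size == segs[1].duration_s


class TestSplit:
    def test_hundred_patients(self):
        ids = [f"p{i}" for i in range(100)]
        train, val, test = split_patients(ids, seed=0)
        assert (len(train), len(val), len(test)) == (81, 9, 10)

    def test_disjoint_exhaustive(self):
        ids = [f"p{i}" for i in range(37)]
        train, val, test = split_patients(ids, seed=1)
        assert set(train) | set(val) | set(test) == set(ids)
        assert not (set(train) & set(val) or set(train) & set(test) or set(val) & set(test))

    def test_deterministic_in_seed(self):
        ids = [f"p{i}" for i in range(20)]
        assert split_patients(ids, seed=3) == split_patients(ids, seed=3)
        assert split_patients(ids, seed=3) != split_patients(ids, seed=4)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_patients(["a"] * 5 + ["b"] * 4, seed=0)


class TestTraining:
    def test_loss_descends(self, default_record_truth):
        record, _ = default_record_truth
        segs = segment_record(record)
        net = build_network(NetConfig(**SMALL), seed=6)
        net, history = train_model(
            net, segs[:6], segs[6:8],
            TrainConfig(max_epochs=3, patience=3, batch_size=3, seed=0),
        )
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_training_deterministic(self, default_record_truth):
        record, _ = default_record_truth
        segs = segment_record(record)
        hashes = []
        for _ in range(2):
            net = build_network(NetConfig(**SMALL), seed=6)
            net, _ = train_model(
                net, segs[:4], segs[4:5],
                TrainConfig(max_epochs=2, patience=3, batch_size=2, seed=0),
            )
            hashes.append(net.weights_hash())
        assert hashes[0] == hashes[1]

    def test_empty_sets_rejected(self):
        net = build_network(NetConfig(**SMALL))
        with pytest.raises(ValueError):
            train_model(net, [], [], TrainConfig())


def test_checkpoint_roundtrip(tmp_path, default_record_truth):
    record, _ = default_record_truth
    seg = segment_record(record)[0]
    net = build_network(NetConfig(**SMALL), seed=9)
    before = predict_segment(net, seg)
    path = save_checkpoint(net, tmp_path / "model.npz")
    restored = load_checkpoint(path)
    after = predict_segment(restored, seg)
    assert np.array_equal(before.values, after.values)
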