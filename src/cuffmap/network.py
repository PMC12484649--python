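"""Causal CNN + cuff-initialized LSTM for continuous MAP estimation.

Architecture, end to end causal:

1. PPG and ECG at 125 Hz pass through a stack of dilated causal
   convolutions (kernel 15, stride 1, dropout 0.2 after each layer,
   dilation doubling per layer, left pad (k-1)*d), giving the encoder a
   receptive field of 1 + (k-1) * (2^L - 1) samples.
2. The encoder output is reduced to 1 Hz by causal average pooling over
   trailing 125-sample windows (stride 125) and concatenated on the
   channel axis with the 1 Hz derived features (HR, PI, NRA).
3. An LSTM consumes the fused sequence.  Instead of a zero initial
   hidden state, h0 is seeded with the segment's opening cuff MAP
   (normalized, broadcast across all hidden units of every layer);
   c0 is zero.  Arrival of a new cuff reading resets the state —
   recalibration without any weight change.
4. A per-timestep affine head maps the hidden state to normalized MAP,
   denormalized to mmHg.

Input features and the MAP target are z-normalized with fixed constants
recorded in :class:`NetConfig`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields

import numpy as np

from .nn import Adam, CausalConv1d, Dropout, LSTM, ReLU, TimeDistributedAffine, TrailingAvgPool
from .records import WAVEFORM_FS
from .segments import Segment

__all__ = [
    "NetConfig",
    "TrainConfig",
    "CalibratedState",
    "PredictionSeries",
    "CausalMapNet",
    "build_network",
    "encode_highfreq",
    "init_calibration_state",
    "recalibrate",
    "predict_segment",
    "split_patients",
    "train_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters and normalization constants."""

    kernel_size: int = 15
    stride: int = 1
    dropout: float = 0.2
    dilation_base: int = 2
    n_conv_layers: int = 8
    conv_channels: int = 32
    lstm_hidden: int = 64
    lstm_layers: int = 1
    #: initial forget-gate bias; near-1 forget gates let the cuff-seeded
    #: state persist across a whole inter-cuff segment
    lstm_forget_bias: float = 5.0
    #: seed h0 from the opening cuff (False = zero-state ablation)
    calibrated: bool = True
    map_norm_center: float = 80.0  # mmHg
    map_norm_scale: float = 20.0  # mmHg
    # per-channel z-normalization (center, scale)
    ppg_norm: tuple[float, float] = (1.0, 0.05)
    ecg_norm: tuple[float, float] = (0.0, 0.3)
    hr_norm: tuple[float, float] = (75.0, 15.0)
    pi_norm: tuple[float, float] = (3.0, 2.0)
    nra_norm: tuple[float, float] = (0.5, 0.2)

    def __post_init__(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("need at least one convolutional layer")
        if self.stride != 1:
            raise ValueError("the dilated stack uses stride 1 throughout")

    @property
    def receptive_field(self) -> int:
        """Encoder receptive field in 125 Hz samples:
        1 + (k - 1) * (base^L - 1) / (base - 1) * (base - 1) for base 2
        reduces to 1 + (k - 1) * (2^L - 1)."""
        b = self.dilation_base
        return 1 + (self.kernel_size - 1) * (b ** self.n_conv_layers - 1) // (b - 1)

    @classmethod
    def small_profile(cls, **overrides) -> "NetConfig":
        """Reduced profile for CPU-scale experiments and CI."""
        base = dict(n_conv_layers=4, conv_channels=8, lstm_hidden=32)
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        payload = ";".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: MSE at 1 Hz, Adam, early stopping on val MAE."""

    lr: float = 2e-3
    #: multiplicative per-epoch decay applied after ``lr_decay_start``
    lr_decay: float = 0.9
    lr_decay_start: int = 5
    batch_size: int = 8
    max_epochs: int = 30
    patience: int = 4
    #: average the weights of the last k epochs (tail averaging flattens
    #: the optimizer's epoch-to-epoch wander); 0 restores the best
    #: single validation epoch instead
    swa_last: int = 0
    clip_norm: float = 5.0
    seed: int = 0


@dataclass
class CalibratedState:
    """Cuff-seeded recurrent state: h0 per layer, c0 zeros."""

    h0: np.ndarray  # (lstm_layers, hidden), broadcast over the batch later
    c0: np.ndarray
    cuff_map: float


@dataclass
class PredictionSeries:
    """1 Hz MAP estimate aligned to a segment, with provenance."""

    values: np.ndarray  # mmHg
    start_s: int
    model_id: str
    config_hash: str
    opening_cuff: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("predictions must be finite")


class CausalMapNet:
    """The estimator network; weights are plain NumPy arrays."""

    def __init__(self, config: NetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        c = config.conv_channels
        self.convs: list[CausalConv1d] = []
        self.acts: list[ReLU] = []
        self.drops: list[Dropout] = []
        c_in = 2
        for layer in range(config.n_conv_layers):
            dilation = config.dilation_base ** layer
            self.convs.append(
                CausalConv1d(c_in, c, config.kernel_size, dilation, rng, dtype)
            )
            self.acts.append(ReLU())
            self.drops.append(Dropout(config.dropout, self._dropout_rng))
            c_in = c
        self.pool = TrailingAvgPool(WAVEFORM_FS)
        self.lstms = [
            LSTM(c + 3 if i == 0 else config.lstm_hidden, config.lstm_hidden, rng,
                 dtype, forget_bias=config.lstm_forget_bias)
            for i in range(config.lstm_layers)
        ]
        self.head = TimeDistributedAffine(config.lstm_hidden, rng, dtype)

    # -- parameter plumbing -------------------------------------------------

    def layers(self):
        return [*self.convs, *self.lstms, self.head]

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads()]

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def weights_hash(self) -> str:
        h = hashlib.sha1()
        for p in self.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()[:16]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def encode(self, ppg: np.ndarray, ecg: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T125) waveform pair -> (B, C, T125) causal embedding
        (before pooling).  Trailing partial seconds are dropped."""
        ppg = np.atleast_2d(np.asarray(ppg, dtype=self.dtype))
        ecg = np.atleast_2d(np.asarray(ecg, dtype=self.dtype))
        t = ppg.shape[1]
        if t % WAVEFORM_FS:
            t -= t % WAVEFORM_FS
            logger.info("dropping trailing partial second (%d samples)", ppg.shape[1] - t)
            ppg, ecg = ppg[:, :t], ecg[:, :t]
        cfg = self.config
        x = np.stack(
            [
                (ppg - cfg.ppg_norm[0]) / cfg.ppg_norm[1],
                (ecg - cfg.ecg_norm[0]) / cfg.ecg_norm[1],
            ],
            axis=1,
        ).astype(self.dtype)
        for conv, act, drop in zip(self.convs, self.acts, self.drops):
            x = drop.forward(act.forward(conv.forward(x)), train=train)
        return x

    def embed_1hz(self, ppg: np.ndarray, ecg: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T125) -> (B, C, T_sec): encoder plus causal pooling to 1 Hz."""
        return self.pool.forward(self.encode(ppg, ecg, train=train))

    def _normalize_feats(self, feats: np.ndarray) -> np.ndarray:
        cfg = self.config
        out = np.empty_like(feats, dtype=self.dtype)
        for i, (c, s) in enumerate((cfg.hr_norm, cfg.pi_norm, cfg.nra_norm)):
            out[:, :, i] = (feats[:, :, i] - c) / s
        return out

    def forward(
        self,
        ppg: np.ndarray,
        ecg: np.ndarray,
        feats: np.ndarray,
        cuff: np.ndarray,
        train: bool = False,
    ) -> np.ndarray:
        """Full pass: waveforms (B, T*125), features (B, T, 3), opening
        cuff (B,) -> MAP estimate in mmHg (B, T)."""
        cfg = self.config
        emb = self.embed_1hz(ppg, ecg, train=train)  # (B, C, T)
        fused = np.concatenate(
            [emb.transpose(0, 2, 1), self._normalize_feats(np.asarray(feats))], axis=2
        ).astype(self.dtype)
        b, t, _ = fused.shape
        h = cfg.lstm_hidden
        if cfg.calibrated:
            h0_scalar = (np.asarray(cuff, dtype=self.dtype) - cfg.map_norm_center) / cfg.map_norm_scale
            h0 = np.broadcast_to(h0_scalar[:, None], (b, h)).astype(self.dtype)
        else:
            h0 = np.zeros((b, h), dtype=self.dtype)
        c0 = np.zeros((b, h), dtype=self.dtype)
        x = fused
        for lstm in self.lstms:
            x = lstm.forward(x, h0, c0, train=train)
        y_norm = self.head.forward(x)
        self._t = t
        return cfg.map_norm_center + cfg.map_norm_scale * y_norm

    def backward(self, dy_norm: np.ndarray) -> None:
        """Backprop from the gradient w.r.t. the *normalized* output."""
        dx = self.head.backward(dy_norm)
        for lstm in reversed(self.lstms):
            dx = lstm.backward(dx)
        c = self.config.conv_channels
        d_emb = dx[:, :, :c].transpose(0, 2, 1)
        d = self.pool.backward(np.ascontiguousarray(d_emb))
        for conv, act, drop in zip(reversed(self.convs), reversed(self.acts), reversed(self.drops)):
            d = conv.backward(act.backward(drop.backward(d)))


CHECKPOINT_VERSION = 1


def save_checkpoint(network: CausalMapNet, path) -> str:
    """Persist weights + config as an ``.npz`` (format version 1)."""
    import json

    cfg = {f.name: getattr(network.config, f.name) for f in fields(network.config)}
    arrays = {f"param_{i}": p for i, p in enumerate(network.params())}
    np.savez(
        str(path),
        __version__=CHECKPOINT_VERSION,
        __config__=json.dumps(cfg),
        **arrays,
    )
    return str(path)


def load_checkpoint(path) -> CausalMapNet:
    """Restore a network saved by :func:`save_checkpoint`."""
    import json

    with np.load(str(path), allow_pickle=False) as data:
        version = int(data["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        cfg_dict = json.loads(str(data["__config__"]))
        for key in ("ppg_norm", "ecg_norm", "hr_norm", "pi_norm", "nra_norm"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = CausalMapNet(NetConfig(**cfg_dict))
        weights = [data[f"param_{i}"] for i in range(len(net.params()))]
        net.set_weights(weights)
    return net


def build_network(config: NetConfig, seed: int = 0) -> CausalMapNet:
    """Instantiate the network; parameter count is a pure function of
    the config, and weights of (config, seed)."""
    return CausalMapNet(config, seed=seed)


def encode_highfreq(network: CausalMapNet, ppg: np.ndarray, ecg: np.ndarray,
                    train: bool = False) -> np.ndarray:
    """1 Hz embedding sequence of a waveform pair: (B, C, T_sec)."""
    return network.embed_1hz(ppg, ecg, train=train)


def init_calibration_state(cuff_map: float, config: NetConfig) -> CalibratedState:
    """Seed the recurrent state from a cuff MAP reading."""
    if not 20.0 <= cuff_map <= 250.0:
        raise ValueError(f"cuff MAP {cuff_map} mmHg outside the accepted 20-250 range")
    h0_val = (cuff_map - config.map_norm_center) / config.map_norm_scale
    h0 = np.full((config.lstm_layers, config.lstm_hidden), h0_val, dtype=np.float32)
    c0 = np.zeros_like(h0)
    return CalibratedState(h0, c0, float(cuff_map))


def recalibrate(state: CalibratedState, new_cuff: float, config: NetConfig) -> CalibratedState:
    """Reset the state wholesale to the new cuff value (no weight change)."""
    return init_calibration_state(new_cuff, config)


# ---------------------------------------------------------------------------
# Segment-level inference and training
# ---------------------------------------------------------------------------


def _segment_inputs(segment: Segment, config: NetConfig):
    """Assemble network inputs from a segment, filling masked samples
    with the channel's normalization center (zero after z-norm)."""

    def fill(ch, center):
        v = ch.values.copy()
        v[ch.missing | ~np.isfinite(v)] = center
        return v

    ppg = fill(segment.ppg, config.ppg_norm[0])[None, :]
    ecg = fill(segment.ecg, config.ecg_norm[0])[None, :]
    feats = np.stack(
        [
            fill(segment.hr, config.hr_norm[0]),
            fill(segment.pi, config.pi_norm[0]),
            fill(segment.nra, config.nra_norm[0]),
        ],
        axis=1,
    )[None, :, :]
    cuff = np.array([segment.opening_cuff.map_mmHg])
    return ppg, ecg, feats, cuff


def predict_segment(network: CausalMapNet, segment: Segment) -> PredictionSeries:
    """Run calibrated inference over one inter-cuff segment.

    Dropout is disabled, so repeated calls give identical output; the
    prediction at second t depends only on inputs at times <= t.
    """
    ppg, ecg, feats, cuff = _segment_inputs(segment, network.config)
    y = network.forward(ppg, ecg, feats, cuff, train=False)[0]
    return PredictionSeries(
        values=np.asarray(y, dtype=np.float64),
        start_s=segment.start_s,
        model_id=type(network).__name__,
        config_hash=network.config.config_hash(),
        opening_cuff=float(segment.opening_cuff.map_mmHg),
    )


def predict_record(network: CausalMapNet, record, min_segment_s: int = 60):
    """Segment a record and predict each segment with its opening cuff.

    Returns (values, missing) 1 Hz arrays over the full record; samples
    outside inter-cuff segments are masked.
    """
    from .segments import segment_record

    n = record.duration_s
    out = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for seg in segment_record(record, min_segment_s=min_segment_s):
        pred = predict_segment(network, seg)
        out[seg.start_s: seg.end_s] = pred.values
        mask[seg.start_s: seg.end_s] = False
    return out, mask


def split_patients(patient_ids: list[str], seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Patient-level train/val/test split: 10% held-out test, then 10%
    of the remainder for validation.  Deterministic in (ids, seed);
    partitions are disjoint and exhaustive."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < 10:
        raise ValueError("need at least 10 patients for a patient-level split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = max(1, round(0.10 * len(ids)))
    rest = len(ids) - n_test
    n_val = max(1, int(np.ceil(0.10 * rest)))
    test = [ids[i] for i in order[:n_test]]
    val = [ids[i] for i in order[n_test:n_test + n_val]]
    train = [ids[i] for i in order[n_test + n_val:]]
    return train, val, test


def _make_batches(segments: list[Segment], config: NetConfig, batch_size: int):
    """Length-bucketed batches of stacked segment tensors."""
    by_len: dict[int, list[Segment]] = {}
    for seg in segments:
        by_len.setdefault(seg.duration_s, []).append(seg)
    batches = []
    for dur in sorted(by_len):
        group = by_len[dur]
        for i in range(0, len(group), batch_size):
            chunk = group[i:i + batch_size]
            ppg = np.concatenate([_segment_inputs(s, config)[0] for s in chunk])
            ecg = np.concatenate([_segment_inputs(s, config)[1] for s in chunk])
            feats = np.concatenate([_segment_inputs(s, config)[2] for s in chunk])
            cuff = np.concatenate([_segment_inputs(s, config)[3] for s in chunk])
            target = np.stack([s.map_ref.values for s in chunk])
            miss = np.stack([s.map_ref.missing | ~np.isfinite(s.map_ref.values) for s in chunk])
            target = np.where(miss, config.map_norm_center, target)
            batches.append((ppg, ecg, feats, cuff, target, ~miss))
    return batches


def _eval_mae(network: CausalMapNet, batches) -> float:
    err_sum, n = 0.0, 0
    for ppg, ecg, feats, cuff, target, ok in batches:
        y = network.forward(ppg, ecg, feats, cuff, train=False)
        err_sum += float(np.abs((y - target))[ok].sum())
        n += int(ok.sum())
    return err_sum / max(n, 1)


def train_model(
    network: CausalMapNet,
    train_segments: list[Segment],
    val_segments: list[Segment],
    train_config: TrainConfig | None = None,
) -> tuple[CausalMapNet, list[dict]]:
    """Minimize masked 1 Hz MSE; early-stop on validation MAE.

    Returns the network with the best-validation weights restored and a
    per-epoch history (train loss in normalized units, val MAE in mmHg).
    Non-finite loss aborts with a diagnostic.
    """
    cfg = train_config or TrainConfig()
    if not train_segments or not val_segments:
        raise ValueError("need non-empty train and validation segment sets")
    rng = np.random.default_rng(cfg.seed)
    net_cfg = network.config
    train_batches = _make_batches(train_segments, net_cfg, cfg.batch_size)
    val_batches = _make_batches(val_segments, net_cfg, cfg.batch_size)
    opt = Adam(network.params(), network.grads(), lr=cfg.lr, clip_norm=cfg.clip_norm)

    history: list[dict] = []
    best_mae, best_weights, bad_epochs = np.inf, network.get_weights(), 0
    tail: list[list[np.ndarray]] = []
    scale = net_cfg.map_norm_scale
    for epoch in range(cfg.max_epochs):
        if epoch > cfg.lr_decay_start:
            opt.lr = cfg.lr * cfg.lr_decay ** (epoch - cfg.lr_decay_start)
        order = rng.permutation(len(train_batches))
        loss_sum, n_samples = 0.0, 0
        for bi in order:
            ppg, ecg, feats, cuff, target, ok = train_batches[bi]
            y = network.forward(ppg, ecg, feats, cuff, train=True)
            resid_norm = (y - target) / scale
            resid_norm[~ok] = 0.0
            n_ok = int(ok.sum())
            loss = float((resid_norm ** 2).sum()) / max(n_ok, 1)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: non-finite loss"
                )
            loss_sum += loss * n_ok
            n_samples += n_ok
            network.zero_grads()
            network.backward((2.0 * resid_norm / max(n_ok, 1)).astype(network.dtype))
            opt.step()
        val_mae = _eval_mae(network, val_batches)
        history.append(
            {"epoch": epoch, "train_loss": loss_sum / max(n_samples, 1), "val_mae": val_mae}
        )
        logger.info("epoch %d: train loss %.4f, val MAE %.2f mmHg",
                    epoch, history[-1]["train_loss"], val_mae)
        if cfg.swa_last > 0:
            tail.append(network.get_weights())
            tail = tail[-cfg.swa_last:]
        if val_mae < best_mae - 1e-4:
            best_mae, best_weights, bad_epochs = val_mae, network.get_weights(), 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    if cfg.swa_last > 0 and len(tail) >= 2:
        # tail averaging is the configured final estimator: a single
        # "best" epoch is a noisy minimum of the validation curve
        averaged = [
            np.mean([w[i] for w in tail], axis=0).astype(tail[0][i].dtype)
            for i in range(len(tail[0]))
        ]
        network.set_weights(averaged)
        swa_mae = _eval_mae(network, val_batches)
        logger.info("tail-averaged weights: val MAE %.2f (best epoch %.2f)", swa_mae, best_mae)
        history.append({"epoch": len(history), "train_loss": np.nan, "val_mae": swa_mae})
        return network, history
    network.set_weights(best_weights)
    return network, history
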