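"""Shared fixtures: seeded synthetic records and the trained estimators.

The heavyweight training fixture is session-scoped: the calibrated
network and its zero-state ablation are trained once on the same
40-patient synthetic cohort and reused by every test that needs a
trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from cuffmap.mechanistic import carry_forward_track
from cuffmap.network import CausalMapNet, NetConfig, TrainConfig, train_model
from cuffmap.segments import filter_segments, segment_record
from cuffmap.simulate import ArtifactSpec, SimParams, generate_record

# seed families for the different cohorts; fixed, non-overlapping
TRAIN_SEEDS = range(100, 140)
VAL_SEEDS = range(200, 206)
TEST_SEEDS = range(300, 310)
EVAL_SEEDS = range(400, 410)
SWEEP_SEEDS = range(500, 510)

#: network / training profile used for CPU-scale experiments
SMALL_NET = dict(n_conv_layers=4, conv_channels=4, lstm_hidden=64)
SMALL_TRAIN = dict(max_epochs=24, patience=24, lr=2e-3, lr_decay=0.92,
                   lr_decay_start=8, batch_size=8, swa_last=4, seed=11)


def make_records(seeds, interval_s: int = 300, **overrides):
    return [
        generate_record(SimParams(seed=s, cuff_interval_s=interval_s, **overrides))[0]
        for s in seeds
    ]


def accepted_segments(records):
    out = []
    for record in records:
        accepted, _ = filter_segments(segment_record(record))
        out += accepted
    return out


@pytest.fixture(scope="session")
def default_record_truth():
    """One default-parameter record with its ground truth (seed 0)."""
    return generate_record(SimParams(seed=0))


@pytest.fixture(scope="session")
def noise_free_record_truth():
    """Noise-free record: exact mechanistic coupling, clean waveforms."""
    return generate_record(SimParams(seed=1, feature_noise_sd=0.0))


@pytest.fixture(scope="session")
def trained_models():
    """Calibrated network + h0-zero ablation trained on 40 patients.

    Returns a dict with both trained networks, the held-out test
    records, the training histories and the carry-forward baseline MAE
    on the held-out records.
    """
    train_recs = make_records(TRAIN_SEEDS)
    val_recs = make_records(VAL_SEEDS)
    test_recs = make_records(TEST_SEEDS)
    train_segs = accepted_segments(train_recs)
    val_segs = accepted_segments(val_recs)

    out = {"test_records": test_recs}
    for name, calibrated in (("calibrated", True), ("ablation", False)):
        net = CausalMapNet(NetConfig(calibrated=calibrated, **SMALL_NET), seed=7)
        net, history = train_model(net, train_segs, val_segs, TrainConfig(**SMALL_TRAIN))
        out[name] = net
        out[name + "_history"] = history
    return out


# ---------------------------------------------------------------------------
# Nine artifact fixtures, each designed to flip exactly one QC criterion
# ---------------------------------------------------------------------------

def criterion_artifacts(start_s: float, length_s: float) -> dict[str, list[ArtifactSpec]]:
    """Artifact specs per criterion for a clean segment at [start, start+length).

    Each entry corrupts a clean segment so that exactly that one
    criterion fails while the other eight keep passing.
    """
    mid = start_s + length_s / 2
    return {
        # whole-segment level shift pushes the mean above 150 without
        # touching dispersion, gradient or sd
        "map_mean": [ArtifactSpec("level_shift", "map_ref", start_s, length_s, 90.0)],
        # smooth 60 s raised-cosine ramp: range > 40 but gradient < 2
        "map_dispersion": [
            ArtifactSpec("level_shift", "map_ref", mid, length_s / 2, 45.0,
                         edge="smooth", ramp_s=60.0)
        ],
        # small hard step mid-segment: one > 2 mmHg jump, range barely moves
        "map_gradient": [ArtifactSpec("level_shift", "map_ref", mid, length_s / 2, 5.0)],
        # flatline removes all MAP variability
        "map_sd": [ArtifactSpec("flatline", "map_ref", start_s, length_s)],
        "map_missing": [ArtifactSpec("missing_run", "map_ref", start_s, 0.3 * length_s)],
        "pi_missing": [ArtifactSpec("missing_run", "pi", start_s, 0.3 * length_s)],
        # constant PI leaves a single distinct value
        "pi_unique": [ArtifactSpec("flatline", "pi", start_s, length_s)],
        "hr_missing": [ArtifactSpec("missing_run", "hr", start_s, 0.3 * length_s)],
        # 2% of the waveform missing breaks the 1% PPG budget
        "ppg_missing": [ArtifactSpec("missing_run", "ppg", start_s, 0.02 * length_s)],
    }
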