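"""Beat detection on the PPG and the three pulse-derived features.

The three features, each resampled to 1 Hz by holding the latest beat's
value (with a 5 s staleness mask):

* HR  — heart rate, 60 / latest inter-foot interval, bpm;
* PI  — perfusion index, 100 x (peak - foot) / DC where DC is the
  beat-mean of the raw PPG, in %;
* NRA — dicrotic-notch relative amplitude,
  (notch - foot) / (peak - foot), dimensionless in [0, 1].

Feet are local minima preceding systolic upstrokes, peaks the per-beat
maximum, and the notch the most prominent local minimum of the falling
edge between a peak and the next foot.  Beats without a detectable
notch are flagged and masked in the NRA output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .records import Channel, PhysioRecord, WAVEFORM_FS

__all__ = [
    "PulseLandmarks",
    "FeatureSet",
    "detect_pulses",
    "compute_hr",
    "compute_pi",
    "compute_nra",
    "extract_features",
]

#: a held feature older than this is considered stale and masked
STALENESS_S = 5.0


@dataclass
class PulseLandmarks:
    """Per-beat landmark times (s) and signal values; notch may be NaN."""

    foot_time: np.ndarray
    peak_time: np.ndarray
    notch_time: np.ndarray
    foot_value: np.ndarray
    peak_value: np.ndarray
    notch_value: np.ndarray
    #: end of each beat (start of the next foot), seconds
    beat_end_time: np.ndarray

    def __post_init__(self) -> None:
        order = (self.foot_time < self.peak_time) & (
            np.isnan(self.notch_time) | (self.peak_time < self.notch_time)
        )
        if not np.all(order):
            raise ValueError("landmarks must satisfy foot < peak < notch per beat")

    def __len__(self) -> int:
        return self.foot_time.size

    @property
    def has_notch(self) -> np.ndarray:
        return ~np.isnan(self.notch_time)


@dataclass
class FeatureSet:
    """HR / PI / NRA at 1 Hz with explicit missing masks."""

    hr: Channel
    pi: Channel
    nra: Channel


def _empty_landmarks() -> PulseLandmarks:
    z = np.empty(0)
    return PulseLandmarks(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


def detect_pulses(
    ppg_125hz: np.ndarray,
    missing: np.ndarray | None = None,
    fs: int = WAVEFORM_FS,
) -> PulseLandmarks:
    """Detect beats and their landmarks on a 125 Hz PPG trace.

    Works per contiguous run of non-missing samples.  A flatline or
    all-missing input yields an empty landmark set rather than an error.
    """
    x = np.asarray(ppg_125hz, dtype=np.float64)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of PPG signal")
    if missing is None:
        missing = np.zeros(x.size, dtype=bool)
    valid = ~np.asarray(missing, dtype=bool) & np.isfinite(x)

    feet, peaks, notches = [], [], []
    fv, pv, nv, ends = [], [], [], []

    # iterate contiguous valid runs
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    starts = [0] if valid[0] else []
    starts += [int(e) + 1 for e in edges if valid[e + 1]]
    stops = [int(e) + 1 for e in edges if valid[e]]
    if valid[-1]:
        stops.append(x.size)

    for lo, hi in zip(starts, stops):
        seg = x[lo:hi]
        if seg.size < fs:  # less than a second: no reliable beat
            continue
        spread = np.percentile(seg, 95) - np.percentile(seg, 5)
        if spread <= 1e-12:
            continue  # flatline
        pk, _ = find_peaks(seg, prominence=0.4 * spread, distance=int(0.3 * fs))
        if pk.size < 2:
            continue
        # foot preceding each peak: minimum since the previous peak
        for i in range(1, pk.size):
            a, b = pk[i - 1], pk[i]
            foot_rel = a + int(np.argmin(seg[a:b]))
            # beat spans [foot_i, foot_{i+1}); peak of the beat is the next max
            if i + 1 < pk.size:
                nxt_foot_rel = pk[i] + int(np.argmin(seg[pk[i]: pk[i + 1]]))
            else:
                nxt_foot_rel = hi - lo - 1
            if nxt_foot_rel <= foot_rel + 2:
                continue
            beat = seg[foot_rel: nxt_foot_rel + 1]
            peak_rel = foot_rel + int(np.argmax(beat))
            if peak_rel <= foot_rel:
                continue
            # notch: most prominent local minimum on the falling edge
            fall = seg[peak_rel: nxt_foot_rel + 1]
            notch_rel = np.nan
            if fall.size >= 5:
                mins, props = find_peaks(-fall, prominence=1e-6 * spread)
                if mins.size:
                    best = mins[int(np.argmax(props["prominences"]))]
                    notch_rel = peak_rel + int(best)
            feet.append((lo + foot_rel) / fs)
            peaks.append((lo + peak_rel) / fs)
            fv.append(seg[foot_rel])
            pv.append(seg[peak_rel])
            ends.append((lo + nxt_foot_rel) / fs)
            if np.isnan(notch_rel):
                notches.append(np.nan)
                nv.append(np.nan)
            else:
                notches.append((lo + notch_rel) / fs)
                nv.append(seg[int(notch_rel)])

    if not feet:
        return _empty_landmarks()
    return PulseLandmarks(
        np.array(feet), np.array(peaks), np.array(notches),
        np.array(fv), np.array(pv), np.array(nv), np.array(ends),
    )


def _hold_at_1hz(
    beat_time: np.ndarray,
    beat_value: np.ndarray,
    n_seconds: int,
    staleness_s: float = STALENESS_S,
) -> Channel:
    """Hold the latest per-beat value on the 1 Hz grid with staleness mask."""
    values = np.full(n_seconds, np.nan)
    miss = np.ones(n_seconds, dtype=bool)
    ok = ~np.isnan(beat_value)
    bt, bv = beat_time[ok], beat_value[ok]
    if bt.size:
        t = np.arange(n_seconds, dtype=np.float64)
        idx = np.searchsorted(bt, t, side="right") - 1
        usable = idx >= 0
        age = np.where(usable, t - bt[np.clip(idx, 0, None)], np.inf)
        usable &= age <= staleness_s
        values[usable] = bv[idx[usable]]
        miss[usable] = False
    return Channel(values, miss, 1.0)


def compute_hr(landmarks: PulseLandmarks, n_seconds: int) -> Channel:
    """1 Hz heart rate from inter-foot intervals (needs >= 2 beats)."""
    if len(landmarks) < 2:
        return Channel(np.full(n_seconds, np.nan), np.ones(n_seconds, dtype=bool), 1.0)
    intervals = np.diff(landmarks.foot_time)
    hr = 60.0 / intervals
    # HR becomes known at the *second* foot of each interval
    return _hold_at_1hz(landmarks.foot_time[1:], hr, n_seconds)


def compute_pi(
    ppg: np.ndarray, landmarks: PulseLandmarks, n_seconds: int, fs: int = WAVEFORM_FS
) -> Channel:
    """1 Hz perfusion index: 100 x (peak - foot) / per-beat DC."""
    x = np.asarray(ppg, dtype=np.float64)
    pis = np.full(len(landmarks), np.nan)
    for i in range(len(landmarks)):
        i0 = int(round(landmarks.foot_time[i] * fs))
        i1 = int(round(landmarks.beat_end_time[i] * fs))
        if i1 <= i0:
            continue
        dc = np.nanmean(x[i0:i1])
        if not np.isfinite(dc) or dc <= 0:
            continue  # non-physical DC: leave masked
        pis[i] = 100.0 * (landmarks.peak_value[i] - landmarks.foot_value[i]) / dc
    return _hold_at_1hz(landmarks.foot_time, pis, n_seconds)


def compute_nra(
    ppg: np.ndarray, landmarks: PulseLandmarks, n_seconds: int
) -> Channel:
    """1 Hz notch relative amplitude, clipped to [0, 1]; masked where no notch."""
    amp = landmarks.peak_value - landmarks.foot_value
    with np.errstate(invalid="ignore", divide="ignore"):
        nra = (landmarks.notch_value - landmarks.foot_value) / amp
    nra = np.where(amp > 0, nra, np.nan)  # degenerate peak == foot -> masked
    nra = np.clip(nra, 0.0, 1.0)
    return _hold_at_1hz(landmarks.foot_time, nra, n_seconds)


def extract_features(record: PhysioRecord) -> FeatureSet:
    """Detect pulses on a record's PPG and compute all three features."""
    n_seconds = record.duration_s
    lm = detect_pulses(record.ppg.values, record.ppg.missing)
    if len(lm) < 2:
        nanch = Channel(np.full(n_seconds, np.nan), np.ones(n_seconds, dtype=bool), 1.0)
        return FeatureSet(nanch, nanch.copy(), nanch.copy())
    return FeatureSet(
        hr=compute_hr(lm, n_seconds),
        pi=compute_pi(record.ppg.values, lm, n_seconds),
        nra=compute_nra(record.ppg.values, lm, n_seconds),
    )
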