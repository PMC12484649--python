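"""Physiological record container and on-disk HDF5 format.

A :class:`PhysioRecord` bundles one patient's synchronized channels:

* high-frequency waveforms (PPG, ECG) at 125 Hz,
* pulse-derived features (HR, PI, NRA) and the arterial-line reference
  MAP at 1 Hz,
* the time-ordered list of intermittent cuff (oscillometric) readings.

Missing data is represented by an explicit boolean mask per channel
rather than sentinel values, so that "missing proportion" quality
filters are unambiguous.  All channels share time origin 0 (seconds
from record start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as _signal

WAVEFORM_FS = 125
DERIVED_FS = 1

__all__ = [
    "WAVEFORM_FS",
    "DERIVED_FS",
    "Channel",
    "CuffEvent",
    "PhysioRecord",
    "RecordFormatError",
    "write_record",
    "read_record",
    "resample_to_125hz",
    "export_channel_csv",
]


class RecordFormatError(ValueError):
    """Raised when an on-disk container is missing a required group."""


@dataclass
class Channel:
    """A uniformly sampled series with an explicit missing mask."""

    values: np.ndarray
    missing: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have equal shape")

    def __len__(self) -> int:
        return self.values.size

    def copy(self) -> "Channel":
        return Channel(self.values.copy(), self.missing.copy(), self.fs)

    @classmethod
    def complete(cls, values: np.ndarray, fs: float) -> "Channel":
        values = np.asarray(values, dtype=np.float64)
        return cls(values, np.zeros(values.shape, dtype=bool), fs)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.missing]

    def missing_fraction(self) -> float:
        if self.values.size == 0:
            return 1.0
        return float(self.missing.mean())


@dataclass(frozen=True)
class CuffEvent:
    """One oscillometric cuff reading: time (s from record start), MAP (mmHg)."""

    time_s: float
    map_mmHg: float

    def __post_init__(self) -> None:
        if not 20.0 <= self.map_mmHg <= 250.0:
            raise ValueError(
                f"cuff MAP {self.map_mmHg:.1f} mmHg outside the plausible "
                "20-250 mmHg range"
            )


@dataclass
class PhysioRecord:
    """One patient's synchronized multichannel physiological record."""

    patient_id: str
    ppg: Channel
    ecg: Channel
    hr: Channel
    pi: Channel
    nra: Channel
    map_ref: Channel
    cuff_events: list[CuffEvent]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n1 = len(self.map_ref)
        for name in ("hr", "pi", "nra"):
            if len(getattr(self, name)) != n1:
                raise ValueError(f"derived channel {name!r} length differs from map_ref")
        for name in ("ppg", "ecg"):
            if len(getattr(self, name)) != n1 * WAVEFORM_FS:
                raise ValueError(
                    f"waveform channel {name!r} must hold "
                    f"{WAVEFORM_FS} samples per second of record"
                )
        times = [e.time_s for e in self.cuff_events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("cuff events must be strictly increasing in time")
        if times and (times[0] < 0 or times[-1] > self.duration_s):
            raise ValueError("cuff events must lie within the record")

    @property
    def duration_s(self) -> int:
        return len(self.map_ref) // DERIVED_FS

    def copy(self) -> "PhysioRecord":
        return PhysioRecord(
            patient_id=self.patient_id,
            ppg=self.ppg.copy(),
            ecg=self.ecg.copy(),
            hr=self.hr.copy(),
            pi=self.pi.copy(),
            nra=self.nra.copy(),
            map_ref=self.map_ref.copy(),
            cuff_events=list(self.cuff_events),
            metadata=dict(self.metadata),
        )

    def channels(self) -> dict[str, Channel]:
        return {
            "ppg": self.ppg,
            "ecg": self.ecg,
            "hr": self.hr,
            "pi": self.pi,
            "nra": self.nra,
            "map_ref": self.map_ref,
        }


# ---------------------------------------------------------------------------
# HDF5 layout:
#   /waveforms/{ppg,ecg}/{value,missing}      @fs = 125
#   /derived/{hr,pi,nra,map_ref}/{value,missing}   @fs = 1
#   /cuff/{time_s,map_mmHg}
#   /meta  (attrs: patient_id, duration_s, free-form metadata)
# ---------------------------------------------------------------------------

_WAVEFORM_NAMES = ("ppg", "ecg")
_DERIVED_NAMES = ("hr", "pi", "nra", "map_ref")


def _write_channel(group: h5py.Group, name: str, ch: Channel) -> None:
    sub = group.create_group(name)
    sub.create_dataset("value", data=ch.values)
    sub.create_dataset("missing", data=ch.missing)
    sub.attrs["fs"] = ch.fs


def _read_channel(group: h5py.Group, name: str, path: str) -> Channel:
    if name not in group:
        raise RecordFormatError(f"container is missing channel {group.name}/{name} in {path}")
    sub = group[name]
    return Channel(sub["value"][()], sub["missing"][()], float(sub.attrs["fs"]))


def write_record(record: PhysioRecord, path) -> str:
    """Write *record* to *path* as a hierarchical HDF5 container."""
    path = str(path)
    with h5py.File(path, "w") as f:
        wf = f.create_group("waveforms")
        for name in _WAVEFORM_NAMES:
            _write_channel(wf, name, getattr(record, name))
        de = f.create_group("derived")
        for name in _DERIVED_NAMES:
            _write_channel(de, name, getattr(record, name))
        cu = f.create_group("cuff")
        cu.create_dataset("time_s", data=np.array([e.time_s for e in record.cuff_events]))
        cu.create_dataset(
            "map_mmHg", data=np.array([e.map_mmHg for e in record.cuff_events])
        )
        meta = f.create_group("meta")
        meta.attrs["patient_id"] = record.patient_id
        meta.attrs["duration_s"] = record.duration_s
        for key, val in record.metadata.items():
            meta.attrs[str(key)] = val
    return path


def read_record(path) -> PhysioRecord:
    """Read a record previously written by :func:`write_record`.

    Raises :class:`RecordFormatError` naming the missing group when the
    container is malformed.
    """
    path = str(path)
    with h5py.File(path, "r") as f:
        for group in ("waveforms", "derived", "cuff", "meta"):
            if group not in f:
                raise RecordFormatError(f"container is missing group /{group} in {path}")
        channels = {}
        for name in _WAVEFORM_NAMES:
            channels[name] = _read_channel(f["waveforms"], name, path)
        for name in _DERIVED_NAMES:
            channels[name] = _read_channel(f["derived"], name, path)
        times = f["cuff"]["time_s"][()]
        maps = f["cuff"]["map_mmHg"][()]
        cuffs = [CuffEvent(float(t), float(m)) for t, m in zip(times, maps)]
        meta_attrs = dict(f["meta"].attrs)
        patient_id = str(meta_attrs.pop("patient_id"))
        meta_attrs.pop("duration_s", None)
    return PhysioRecord(
        patient_id=patient_id,
        cuff_events=cuffs,
        metadata=meta_attrs,
        **channels,
    )


def resample_to_125hz(waveform: np.ndarray, native_fs: int) -> np.ndarray:
    """Anti-aliased decimation of a waveform to the 125 Hz working rate.

    Supported native rates are 125 (identity), 250 and 500 Hz.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if native_fs == 125:
        return waveform
    if native_fs not in (250, 500):
        raise ValueError(f"unsupported native sampling rate {native_fs} Hz "
                         "(expected 125, 250 or 500)")
    q = native_fs // 125
    return _signal.decimate(waveform, q, ftype="fir", zero_phase=True)


def export_channel_csv(record: PhysioRecord, channel: str, path) -> str:
    """Export one channel as ``time,value,missing`` CSV."""
    import pandas as pd

    ch = record.channels()[channel]
    t = np.arange(len(ch)) / ch.fs
    frame = pd.DataFrame(
        {"time": t, "value": ch.values, "missing": ch.missing.astype(int)}
    )
    frame.to_csv(str(path), index=False)
    return str(path)


def record_equal(a: PhysioRecord, b: PhysioRecord) -> bool:
    """Channel-by-channel equality including missing masks (roundtrip check)."""
    if a.patient_id != b.patient_id or len(a.cuff_events) != len(b.cuff_events):
        return False
    for ea, eb in zip(a.cuff_events, b.cuff_events):
        if ea.time_s != eb.time_s or ea.map_mmHg != eb.map_mmHg:
            return False
    for name, ch in a.channels().items():
        other = b.channels()[name]
        if not (
            np.array_equal(ch.values, other.values)
            and np.array_equal(ch.missing, other.missing)
            and ch.fs == other.fs
        ):
            return False
    return True
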