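"""Inter-cuff segmentation and the nine-criterion segment quality filter.

A segment — the unit of inference — is all data between two consecutive
cuff readings, half-open ``[cuff_i, cuff_{i+1})``, carrying the opening
cuff as its calibration value.  Before training, segments are screened
with nine simultaneous criteria on the reference MAP, the derived
features and the PPG:

====================  =======================================
criterion             acceptance condition
====================  =======================================
map_mean              50 mmHg < segment MAP mean < 150 mmHg
map_dispersion        MAP range (max - min) < 40 mmHg
map_gradient          max |dMAP/dt| at 1 Hz < 2 mmHg/s
map_sd                MAP standard deviation > 1 mmHg
map_missing           MAP missing proportion < 20 %
pi_missing            PI missing proportion < 20 %
pi_unique             distinct unmasked PI values > 5
hr_missing            HR missing proportion < 20 %
ppg_missing           PPG missing proportion < 1 %
====================  =======================================

"Dispersion" is interpreted as the range (max - min) in mmHg,
consistent with screening on extremum values; the gradient is the
maximum absolute first difference of the 1 Hz reference MAP.  The
printed inequality directions are applied strictly (e.g. the sd must
exceed 1, not merely reach it).  MAP-based criteria act on the arterial
reference and therefore apply at training time; at pure inference time
they can be skipped and are flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .records import Channel, CuffEvent, PhysioRecord, WAVEFORM_FS

__all__ = [
    "Segment",
    "FilterCriteria",
    "CriterionResult",
    "QualityReport",
    "MIN_SEGMENT_S",
    "segment_record",
    "compute_quality_metrics",
    "filter_segments",
]

logger = logging.getLogger(__name__)

#: irregular cuff schedules can produce very short inter-cuff gaps;
#: anything shorter than this is not a usable inference window
MIN_SEGMENT_S = 60

#: names of the MAP-based criteria (skippable at pure inference time)
MAP_CRITERIA = ("map_mean", "map_dispersion", "map_gradient", "map_sd", "map_missing")


@dataclass
class Segment:
    """All channels between two consecutive cuff events."""

    patient_id: str
    start_s: int
    end_s: int
    opening_cuff: CuffEvent
    ppg: Channel
    ecg: Channel
    hr: Channel
    pi: Channel
    nra: Channel
    map_ref: Channel

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")
        if int(self.opening_cuff.time_s) != self.start_s:
            raise ValueError("opening cuff must coincide with segment start")
        n = self.end_s - self.start_s
        for name in ("hr", "pi", "nra", "map_ref"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"derived slice {name!r} length mismatch")
        for name in ("ppg", "ecg"):
            if len(getattr(self, name)) != n * WAVEFORM_FS:
                raise ValueError(f"waveform slice {name!r} length mismatch")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the nine-segment filter (defaults as printed)."""

    map_mean_low: float = 50.0
    map_mean_high: float = 150.0
    map_dispersion_max: float = 40.0
    map_gradient_max: float = 2.0
    map_sd_min: float = 1.0
    map_missing_max: float = 0.20
    pi_missing_max: float = 0.20
    pi_unique_min: int = 5
    hr_missing_max: float = 0.20
    ppg_missing_max: float = 0.01

    def log_overrides(self) -> None:
        default = FilterCriteria()
        for f in fields(self):
            if getattr(self, f.name) != getattr(default, f.name):
                logger.info(
                    "filter criterion %s overridden: %r (default %r)",
                    f.name, getattr(self, f.name), getattr(default, f.name),
                )


@dataclass(frozen=True)
class CriterionResult:
    name: str
    value: float
    passed: bool


@dataclass
class QualityReport:
    """Per-criterion metric values and pass flags for one segment."""

    criteria: dict[str, CriterionResult]
    skipped: tuple[str, ...] = ()

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.criteria.values())

    @property
    def rejection_reasons(self) -> list[str]:
        return [name for name, c in self.criteria.items() if not c.passed]


def segment_record(record: PhysioRecord, min_segment_s: int = MIN_SEGMENT_S) -> list[Segment]:
    """Cut a record into inter-cuff segments.

    One segment per consecutive cuff pair, half-open on the right;
    trailing data after the last cuff is discarded.  Fewer than two
    cuffs yields an empty list with a logged warning.  Gaps shorter
    than ``min_segment_s`` are dropped.
    """
    cuffs = record.cuff_events
    if len(cuffs) < 2:
        logger.warning(
            "record %s has %d cuff event(s); need >= 2 to segment",
            record.patient_id, len(cuffs),
        )
        return []
    n = record.duration_s
    out = []
    for a, b in zip(cuffs, cuffs[1:]):
        start, end = int(a.time_s), min(int(b.time_s), n)
        if end - start < min_segment_s:
            continue
        w0, w1 = start * WAVEFORM_FS, end * WAVEFORM_FS

        def slc(ch: Channel, lo: int, hi: int) -> Channel:
            return Channel(ch.values[lo:hi], ch.missing[lo:hi], ch.fs)

        out.append(
            Segment(
                patient_id=record.patient_id,
                start_s=start,
                end_s=end,
                opening_cuff=a,
                ppg=slc(record.ppg, w0, w1),
                ecg=slc(record.ecg, w0, w1),
                hr=slc(record.hr, start, end),
                pi=slc(record.pi, start, end),
                nra=slc(record.nra, start, end),
                map_ref=slc(record.map_ref, start, end),
            )
        )
    return out


def compute_quality_metrics(
    segment: Segment,
    criteria: FilterCriteria | None = None,
    skip_map_criteria: bool = False,
) -> QualityReport:
    """Compute the nine filter metrics (on unmasked samples) for a segment.

    A fully masked MAP yields missing proportion 1.0 and marks the other
    MAP metrics as undefined-and-failing (value NaN).  With
    ``skip_map_criteria`` (pure inference: no arterial reference) the
    MAP-based criteria are recorded as passed and flagged in
    ``QualityReport.skipped``.
    """
    c = criteria or FilterCriteria()
    res: dict[str, CriterionResult] = {}

    m = segment.map_ref
    map_missing = m.missing_fraction()
    valid = m.valid_values()

    def add(name: str, value: float, passed: bool) -> None:
        res[name] = CriterionResult(name, float(value), bool(passed))

    if valid.size:
        mean = valid.mean()
        disp = float(np.ptp(valid))
        sd = float(valid.std())
        both = ~m.missing
        # gradient only over adjacent unmasked pairs
        pair = both[1:] & both[:-1]
        grad = float(np.max(np.abs(np.diff(m.values)[pair]))) if pair.any() else 0.0
        add("map_mean", mean, c.map_mean_low < mean < c.map_mean_high)
        add("map_dispersion", disp, disp < c.map_dispersion_max)
        add("map_gradient", grad, grad < c.map_gradient_max)
        add("map_sd", sd, sd > c.map_sd_min)
    else:
        for name in ("map_mean", "map_dispersion", "map_gradient", "map_sd"):
            add(name, np.nan, False)
    add("map_missing", map_missing, map_missing < c.map_missing_max)

    pi_missing = segment.pi.missing_fraction()
    add("pi_missing", pi_missing, pi_missing < c.pi_missing_max)
    n_unique = int(np.unique(segment.pi.valid_values()).size)
    add("pi_unique", n_unique, n_unique > c.pi_unique_min)
    hr_missing = segment.hr.missing_fraction()
    add("hr_missing", hr_missing, hr_missing < c.hr_missing_max)
    ppg_missing = segment.ppg.missing_fraction()
    add("ppg_missing", ppg_missing, ppg_missing < c.ppg_missing_max)

    skipped: tuple[str, ...] = ()
    if skip_map_criteria:
        skipped = MAP_CRITERIA
        for name in MAP_CRITERIA:
            res[name] = CriterionResult(name, res[name].value, True)
    return QualityReport(res, skipped)


def filter_segments(
    segments: list[Segment],
    criteria: FilterCriteria | None = None,
    skip_map_criteria: bool = False,
) -> tuple[list[Segment], list[tuple[Segment, list[str]]]]:
    """Partition segments into (accepted, rejected-with-reasons).

    A segment is accepted iff all nine criteria pass simultaneously;
    rejection reasons enumerate every failed criterion.  Decisions are
    written to the module logger.
    """
    c = criteria or FilterCriteria()
    c.log_overrides()
    accepted, rejected = [], []
    for seg in segments:
        report = compute_quality_metrics(seg, c, skip_map_criteria=skip_map_criteria)
        if report.overall_pass:
            accepted.append(seg)
            logger.debug("segment %s[%d,%d) accepted", seg.patient_id, seg.start_s, seg.end_s)
        else:
            reasons = report.rejection_reasons
            rejected.append((seg, reasons))
            logger.info(
                "segment %s[%d,%d) rejected: %s",
                seg.patient_id, seg.start_s, seg.end_s, ", ".join(reasons),
            )
    return accepted, rejected
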