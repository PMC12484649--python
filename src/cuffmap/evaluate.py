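"""Error metrics, AAMI/BHS verdicts, per-patient aggregation, sweeps.

Two international validation standards are implemented:

* AAMI: a device passes if |mean error| <= 5 mmHg, the standard
  deviation of the error is <= 8 mmHg, and the test population has at
  least 85 subjects.
* BHS grading, from the cumulative percentages of absolute errors at
  or below 5 / 10 / 15 mmHg: grade A requires (60, 85, 95) %, grade B
  (50, 75, 90) %, grade C (40, 65, 85) %; anything less is below C.

Error dispersion uses the population standard deviation (ddof = 0);
this convention is fixed here and asserted in the tests.  Study-level
results pool errors within each patient first, then average the
per-patient summaries across patients.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ErrorSummary",
    "CumulativePcts",
    "StandardsVerdict",
    "LatencyReport",
    "compute_errors",
    "cumulative_error_pct",
    "bhs_grade",
    "aami_check",
    "standards_verdict",
    "aggregate_per_patient",
    "calibration_sweep",
    "latency_benchmark",
]

logger = logging.getLogger(__name__)

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)
#: minimum cumulative percentages (pct<=5, pct<=10, pct<=15) per grade
BHS_GRADE_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}
AAMI_ME_MAX = 5.0
AAMI_SD_MAX = 8.0
AAMI_MIN_SUBJECTS = 85


@dataclass(frozen=True)
class ErrorSummary:
    """Signed/absolute error summaries of predictions vs the reference."""

    me: float
    mae: float
    sd_error: float
    mae_sd: float
    n_samples: int
    n_patients: int = 1

    def __post_init__(self) -> None:
        if self.mae + 1e-12 < abs(self.me):
            raise ValueError("MAE cannot be smaller than |ME|")


@dataclass(frozen=True)
class CumulativePcts:
    """% of absolute errors at or below 5 / 10 / 15 mmHg."""

    pct_le_5: float
    pct_le_10: float
    pct_le_15: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_le_5 <= self.pct_le_10 <= self.pct_le_15 <= 100:
            raise ValueError("cumulative percentages must be monotone in [0, 100]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pct_le_5, self.pct_le_10, self.pct_le_15)


@dataclass(frozen=True)
class StandardsVerdict:
    aami_pass: bool
    aami_me_ok: bool
    aami_sd_ok: bool
    aami_n_ok: bool
    bhs_grade: str  # "A" | "B" | "C" | "below_C"


@dataclass(frozen=True)
class LatencyReport:
    mean_batch_ms: float
    sd_batch_ms: float
    mean_per_sample_ms: float
    n_batches: int


def compute_errors(
    predictions: np.ndarray,
    reference: np.ndarray,
    missing: np.ndarray | None = None,
    n_patients: int = 1,
) -> ErrorSummary:
    """Summarize prediction - reference over unmasked, finite samples."""
    predictions = np.asarray(predictions, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if predictions.shape != reference.shape:
        raise ValueError("prediction and reference series must be aligned")
    ok = np.isfinite(predictions) & np.isfinite(reference)
    if missing is not None:
        ok &= ~np.asarray(missing, dtype=bool)
    if not ok.any():
        raise ValueError("no overlapping unmasked samples to compare")
    err = predictions[ok] - reference[ok]
    abs_err = np.abs(err)
    return ErrorSummary(
        me=float(err.mean()),
        mae=float(abs_err.mean()),
        sd_error=float(err.std()),  # population sd, ddof=0
        mae_sd=float(abs_err.std()),
        n_samples=int(err.size),
        n_patients=n_patients,
    )


def cumulative_error_pct(
    abs_errors: np.ndarray, thresholds: tuple[float, ...] = BHS_THRESHOLDS_MMHG
) -> CumulativePcts:
    """Percentage of absolute errors at or below each threshold."""
    abs_errors = np.asarray(abs_errors, dtype=np.float64)
    if abs_errors.size == 0:
        raise ValueError("need at least one error sample")
    pcts = tuple(100.0 * float((abs_errors <= t).mean()) for t in thresholds)
    return CumulativePcts(*pcts)


def bhs_grade(pcts: CumulativePcts) -> str:
    """Best BHS grade whose all three band thresholds are met."""
    observed = pcts.as_tuple()
    for grade in ("A", "B", "C"):
        if all(o >= t for o, t in zip(observed, BHS_GRADE_TABLE[grade])):
            return grade
    return "below_C"


def aami_check(summary: ErrorSummary, n_subjects: int) -> tuple[bool, bool, bool, bool]:
    """AAMI verdict: (pass, me_ok, sd_ok, n_ok), inclusive bounds."""
    me_ok = abs(summary.me) <= AAMI_ME_MAX
    sd_ok = summary.sd_error <= AAMI_SD_MAX
    n_ok = n_subjects >= AAMI_MIN_SUBJECTS
    return (me_ok and sd_ok and n_ok, me_ok, sd_ok, n_ok)


def standards_verdict(
    summary: ErrorSummary, pcts: CumulativePcts, n_subjects: int
) -> StandardsVerdict:
    ok, me_ok, sd_ok, n_ok = aami_check(summary, n_subjects)
    return StandardsVerdict(ok, me_ok, sd_ok, n_ok, bhs_grade(pcts))


def aggregate_per_patient(per_segment_results: pd.DataFrame) -> pd.DataFrame:
    """Pool errors within patient, then summarize across patients.

    Input: DataFrame with columns ``patient_id`` and ``error`` (one row
    per 1 Hz sample, signed error in mmHg).  Output: one row per
    patient (me, mae, sd_error, pct_le_*) plus a final ``study`` row
    holding across-patient means (and sds as ``*_sd`` columns).
    Patients contributing zero samples are excluded (logged).
    """
    if not {"patient_id", "error"} <= set(per_segment_results.columns):
        raise ValueError("expected columns patient_id and error")
    rows = []
    for pid, group in per_segment_results.groupby("patient_id", sort=True):
        err = group["error"].to_numpy(dtype=np.float64)
        err = err[np.isfinite(err)]
        if err.size == 0:
            logger.info("patient %s excluded: no valid samples", pid)
            continue
        abs_err = np.abs(err)
        pcts = cumulative_error_pct(abs_err)
        rows.append(
            {
                "patient_id": pid,
                "n_samples": err.size,
                "me": err.mean(),
                "mae": abs_err.mean(),
                "sd_error": err.std(),
                "pct_le_5": pcts.pct_le_5,
                "pct_le_10": pcts.pct_le_10,
                "pct_le_15": pcts.pct_le_15,
            }
        )
    if not rows:
        raise ValueError("no patient had valid samples")
    table = pd.DataFrame(rows)
    metric_cols = ["me", "mae", "sd_error", "pct_le_5", "pct_le_10", "pct_le_15"]
    study = {"patient_id": "study", "n_samples": int(table["n_samples"].sum())}
    for col in metric_cols:
        study[col] = table[col].mean()
        study[col + "_sd"] = table[col].std(ddof=0)
    return pd.concat([table, pd.DataFrame([study])], ignore_index=True)


def evaluate_predictor(predictor, records) -> pd.DataFrame:
    """Per-sample error table for a record-level predictor.

    ``predictor(record) -> (values, missing)`` at 1 Hz.  Skips records
    where prediction and reference never overlap.
    """
    frames = []
    for record in records:
        values, missing = predictor(record)
        ok = (
            ~np.asarray(missing, dtype=bool)
            & ~record.map_ref.missing
            & np.isfinite(values)
        )
        if not ok.any():
            logger.warning("record %s: no overlapping samples", record.patient_id)
            continue
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": record.patient_id,
                    "error": values[ok] - record.map_ref.values[ok],
                }
            )
        )
    if not frames:
        raise ValueError("predictor produced no comparable samples")
    return pd.concat(frames, ignore_index=True)


def calibration_sweep(
    predictor_factory,
    record_factory,
    intervals_s: tuple[int, ...] = (180, 300, 600),
) -> pd.DataFrame:
    """Evaluate a predictor at several cuff-calibration intervals.

    ``record_factory(interval_s)`` returns the evaluation records for
    one cuff interval (regenerating the same underlying physiology with
    the interval changed keeps the comparison paired);
    ``predictor_factory(interval_s)`` returns the record-level
    predictor.  Emits one row per interval: ME, MAE, error sd,
    cumulative percentages and BHS grade, aggregated per patient.
    """
    rows = []
    for interval in intervals_s:
        records = record_factory(interval)
        predictor = predictor_factory(interval)
        table = evaluate_predictor(predictor, records)
        study = aggregate_per_patient(table).iloc[-1]
        pcts = CumulativePcts(study["pct_le_5"], study["pct_le_10"], study["pct_le_15"])
        rows.append(
            {
                "interval_s": interval,
                "me": study["me"],
                "mae": study["mae"],
                "mae_sd": study["mae_sd"],
                "sd_error": study["sd_error"],
                "pct_le_5": pcts.pct_le_5,
                "pct_le_10": pcts.pct_le_10,
                "pct_le_15": pcts.pct_le_15,
                "bhs_grade": bhs_grade(pcts),
                "n_patients": int((aggregate_per_patient(table).shape[0]) - 1),
            }
        )
    return pd.DataFrame(rows)


def latency_benchmark(model_fn, batches, min_batches: int = 15) -> LatencyReport:
    """Wall-clock inference latency per batch and per sample.

    Reporting only — latency is hardware-bound and never an acceptance
    surface.  ``model_fn(batch)`` runs one inference; each batch's
    sample count is ``len(batch)`` or its first array's length.
    """
    if len(batches) < min_batches:
        raise ValueError(f"need at least {min_batches} batches, got {len(batches)}")
    def _batch_samples(batch) -> int:
        item = batch[0] if isinstance(batch, (tuple, list)) and len(batch) else batch
        if hasattr(item, "duration_s"):  # a Segment: one sample per second
            return int(item.duration_s) * (len(batch) if isinstance(batch, (tuple, list)) else 1)
        try:
            return len(item)
        except TypeError:
            return 1

    model_fn(batches[0])  # warm-up, excluded
    times_ms, per_sample = [], []
    for batch in batches:
        n = _batch_samples(batch)
        t0 = time.perf_counter()
        model_fn(batch)
        dt_ms = (time.perf_counter() - t0) * 1e3
        times_ms.append(dt_ms)
        per_sample.append(dt_ms / max(n, 1))
    t = np.asarray(times_ms)
    return LatencyReport(
        mean_batch_ms=float(t.mean()),
        sd_batch_ms=float(t.std()),
        mean_per_sample_ms=float(np.mean(per_sample)),
        n_batches=len(batches),
    )
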