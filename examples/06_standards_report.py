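"""Score a predictor against the AAMI and BHS validation standards.

Evaluates the cuff-recalibrated mechanistic tracker on a small
synthetic cohort, aggregates errors per patient, and prints the
standards verdict.
"""

import numpy as np

from cuffmap import SimParams, generate_record
from cuffmap.evaluate import (
    CumulativePcts,
    ErrorSummary,
    aggregate_per_patient,
    bhs_grade,
    evaluate_predictor,
    standards_verdict,
)
from cuffmap.mechanistic import mechanistic_track

records = [generate_record(SimParams(seed=s))[0] for s in range(6)]
table = evaluate_predictor(mechanistic_track, records)
agg = aggregate_per_patient(table)
study = agg.iloc[-1]

pcts = CumulativePcts(study["pct_le_5"], study["pct_le_10"], study["pct_le_15"])
summary = ErrorSummary(
    me=study["me"], mae=study["mae"], sd_error=study["sd_error"],
    mae_sd=study["mae_sd"], n_samples=int(study["n_samples"]),
)
verdict = standards_verdict(summary, pcts, n_subjects=len(records))

print(agg.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nME {study['me']:+.2f} mmHg, MAE {study['mae']:.2f} mmHg, "
      f"error sd {study['sd_error']:.2f} mmHg")
print(f"errors <=5/10/15 mmHg: {pcts.pct_le_5:.1f}/{pcts.pct_le_10:.1f}/{pcts.pct_le_15:.1f} %")
print(f"BHS grade: {bhs_grade(pcts)}  (A needs 60/85/95)")
print(f"AAMI: |ME|<=5 {verdict.aami_me_ok}, sd<=8 {verdict.aami_sd_ok}, "
      f"n>=85 subjects {verdict.aami_n_ok} -> pass={verdict.aami_pass}")
print("(the subject-count arm fails here simply because the demo cohort "
      "has 6 patients, not 85)")
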