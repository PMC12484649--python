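"""Generate one synthetic intraoperative record and inspect it.

Builds a one-hour patient record (125 Hz PPG/ECG, 1 Hz derived features
and arterial reference MAP, cuff readings every 5 minutes) and prints
summary statistics plus the cuff-vs-arterial residuals.
"""

import numpy as np

from cuffmap import SimParams, generate_record

params = SimParams(seed=42)
record, truth = generate_record(params)

print(f"patient {record.patient_id}: {record.duration_s} s, "
      f"{len(record.cuff_events)} cuff readings")
print(f"MAP     mean {record.map_ref.values.mean():6.1f} mmHg, "
      f"sd {record.map_ref.values.std():4.1f} mmHg")
print(f"HR      mean {record.hr.values.mean():6.1f} bpm")
print(f"PI      mean {record.pi.values.mean():6.2f} %")
print(f"NRA     mean {record.nra.values.mean():6.2f}")

resid = [ev.map_mmHg - record.map_ref.values[min(int(ev.time_s), record.duration_s - 1)]
         for ev in record.cuff_events]
print(f"cuff - arterial residuals: mean {np.mean(resid):+.2f}, sd {np.std(resid):.2f} mmHg "
      "(additive Gaussian cuff-error model, sigma 3.1)")
print(f"true patient coupling: {truth.true_mech_params}")
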