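"""Detect pulses on the synthetic PPG and recover HR / PI / NRA.

The generator encodes the three pulse-derived features into the beat
morphology; the detector should read them back.  The printout compares
the extracted 1 Hz series against the latent ground truth.
"""

import numpy as np

from cuffmap import SimParams, generate_record
from cuffmap.pulses import extract_features

record, truth = generate_record(SimParams(seed=7, feature_noise_sd=0.0))
features = extract_features(record)

for name, channel, latent in [
    ("HR (bpm)", features.hr, truth.hr_latent),
    ("PI (%)", features.pi, truth.pi_latent),
    ("NRA", features.nra, truth.nra_latent),
]:
    ok = ~channel.missing
    err = np.abs(channel.values[ok] - latent[ok])
    print(f"{name:9s} recovered on {ok.mean():5.1%} of seconds; "
          f"median |error| {np.median(err):.3f}, p95 {np.percentile(err, 95):.3f}")
print("Small errors mean the beat-template morphology encodes the features "
      "faithfully and the detector reads them back.")
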