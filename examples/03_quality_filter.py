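"""Segment a record between cuffs and run the nine-criterion filter.

Clean synthetic segments pass; injected artifacts (a missing run on the
reference MAP and a flatlined perfusion index) are rejected with named
reasons.
"""

from cuffmap import ArtifactSpec, SimParams, generate_record, inject_artifacts
from cuffmap.segments import filter_segments, segment_record

record, _ = generate_record(SimParams(seed=3))
accepted, rejected = filter_segments(segment_record(record))
print(f"clean record: {len(accepted)} accepted, {len(rejected)} rejected")

corrupted = inject_artifacts(
    record,
    [
        ArtifactSpec("missing_run", "map_ref", start_s=300.0, length_s=90.0),
        ArtifactSpec("flatline", "pi", start_s=900.0, length_s=300.0),
    ],
)
accepted, rejected = filter_segments(segment_record(corrupted))
print(f"after artifacts: {len(accepted)} accepted, {len(rejected)} rejected")
for seg, reasons in rejected:
    print(f"  segment [{seg.start_s:4d}, {seg.end_s:4d}) rejected: {', '.join(reasons)}")
print("Each rejection lists every failed criterion, e.g. map_missing for the "
      "30% gap and pi_unique for the flatlined PI.")
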