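"""Simulate one 60-min home-cage LFP+EMG session and write it to disk.

The session has theta (6-12 Hz) and beta (15-30 Hz) oscillations over a
1/f background, a drug administration at the 30-min mark, and two
movement-artifact epochs.
"""

from pathlib import Path

from sdsephys import synth, trace_io

cfg = synth.LfpSimConfig(
    duration_s=3600.0,
    fs_hz=2000.0,
    drug_time_s=1800.0,
    artifact_epochs=(
        synth.ArtifactEpoch(600.0, 2.0, 5.0, 5.0),
        synth.ArtifactEpoch(2400.0, 1.5, 5.0, 5.0),
    ),
    seed=1,
)
rec, truth = synth.simulate_lfp_session(cfg)

out = Path("scratch")
out.mkdir(exist_ok=True)
trace_io.write_recording(rec, out / "session.edf")

print(f"channels : {list(rec.channels)} at {rec.fs_hz:.0f} Hz")
print(f"duration : {rec.duration_s:.0f} s, drug at {rec.markers['drug_admin']:.0f} s")
print(f"artifacts: bins {truth.artifact_bins.tolist()} (1-s bins)")
print(f"wrote    : {out / 'session.edf'} (+ .json sidecar)")
# The ground truth lists every injected artifact bin and the per-band
# amplitude schedule, so downstream estimates can be checked against it.
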