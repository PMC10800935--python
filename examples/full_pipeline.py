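"""End-to-end run: simulate -> preprocess -> analyze -> statistics.

A three-arm study (vehicle / diazepam / allopregnanolone) across all three
modalities, driven by one seeded config.  Equivalent shell command:

    ephys-sds run-all --seed 11 --out scratch/run
"""

import json

from sdsephys import pipeline

cfg = pipeline.RunConfig(
    seed=11,
    n_mice_per_arm=3,
    n_cells_per_arm=2,
    output_dir="scratch/run",
)
report = pipeline.run_pipeline(cfg)

print(json.dumps(report.summary, indent=1, sort_keys=True))
print(f"\nconfig hash: {report.manifest['config_hash']}")
print("tables written:", ", ".join(report.tables))
# Expected pattern: allopregnanolone raises theta and beta post/pre ratios
# and shows ~15 pA tonic potentiation; diazepam raises beta only with ~0 pA
# potentiation; vehicle sits near 1.0 / 0 pA.
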