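"""One-call run of the whole synthetic analysis with a hashed manifest.

Simulation, signature scoring, stratification, aggregation, ensemble
classification, integrated scoring, IHC comparison and survival cutpoint
analysis run under a single seeded configuration; rerunning with the same
configuration reproduces identical output hashes.
"""

import json

from lactopath import pipeline

cfg = pipeline.RunConfig(
    out_dir="pipeline_demo",
    seed=7,
    n_genes=600,
    n_samples=60,
    patches_per_slide=(20, 30),
    epochs=2,
    components=16,
)
manifest = pipeline.run_pipeline(cfg)

for stage, entry in manifest["stages"].items():
    print(f"[{stage}]")
    print(json.dumps(entry["metrics"], indent=2, default=str))
print("outputs and SHA-256 hashes recorded in pipeline_demo/manifest.json")
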