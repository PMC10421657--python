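"""Run the whole analysis end to end and inspect the output bundle."""

import json
import tempfile
from pathlib import Path

import ighrep as ir

out = Path(tempfile.mkdtemp(prefix="ighrep_"))
config = ir.PipelineConfig(
    synthetic=ir.SyntheticConfig(seed=6).scaled_richness(0.012),
    permanova_permutations=99999,
    seed=6,
)
summary = ir.run_pipeline(config, out)

print("outputs written to", out)
for path in sorted(out.iterdir()):
    print(" ", path.name)

print("\nsummary.json:")
print(json.dumps(summary, indent=2, sort_keys=True))
print("\nRe-running with the same config and seed reproduces every file "
      "byte for byte; the manifest records the config needed to do so.")
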