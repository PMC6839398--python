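"""Run the full pipeline end to end and inspect the manifest.

Generates WT and Yq-deletion populations, measures profiles and
morphometrics, builds consensus outlines, clusters, summarizes cluster sex
composition, and runs the swim-up statistics — writing every intermediate
as CSV/SVG plus a manifest with derived per-stage seeds and output
digests.
"""

import json
import tempfile
from pathlib import Path

from spermshape import RunConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp(prefix="spermshape_"))
config = RunConfig(seed=1, n_cells=150, out_dir=str(out_dir))
manifest = run_pipeline(config)

print(f"outputs in {out_dir}:")
for name in sorted(manifest["outputs"]):
    print(f"  {name}")
print("\nstage seeds:", manifest["stage_seeds"])
print("\nsummary:")
print(json.dumps(manifest["summary"], indent=2))
print("\nRe-running with the same seed reproduces identical output digests.")
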