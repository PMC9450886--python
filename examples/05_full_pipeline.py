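"""Run the end-to-end pipeline and inspect the run manifest.

Simulates a cohort, extracts/loads features, clusters day 1, assigns day 2,
runs the statistics, and writes every intermediate table plus a manifest
that makes the run exactly reproducible.
"""

import json
from pathlib import Path
from tempfile import mkdtemp

from fishclust import PipelineConfig, run_pipeline

out = Path(mkdtemp()) / "run"
config = PipelineConfig(
    seed=11,
    k=114,
    mode="features",
    m_resamples=10_000,
)
manifest = run_pipeline(config, out)

print("outputs written to", out)
for f in sorted(p.relative_to(out).as_posix() for p in out.rglob("*") if p.is_file()):
    print("  ", f)
print("\nmanifest stages:")
print(json.dumps(manifest.stages, indent=2))
print(
    "\nThe manifest records per-stage row counts, the fitted k, community"
    "\nsizes, and the two-day overlap result; re-running with the same config"
    "\nreproduces every file byte-for-byte."
)
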