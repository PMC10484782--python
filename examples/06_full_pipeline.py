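"""Run the full pipeline: simulate -> classify -> burden -> meta -> frr.

Every stage writes TSV into the run directory and the manifest records a
checksum per output; rerunning with the same configuration is
byte-identical.
"""

import json
import tempfile
from pathlib import Path

from rvburden.pipeline import demo_config, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    outdir = Path(tmp) / "run"
    config = demo_config(str(outdir), seed=3)
    config.n_cases = config.n_controls = 1500
    manifest = run_pipeline(config)
    rerun = run_pipeline(config)

    print("stages executed:", ", ".join(manifest.stages))
    print("outputs:", ", ".join(sorted(manifest.checksums)))
    fit = json.loads((outdir / "frr_fit.json").read_text())
    print(f"fitted mixture on the demo cohort: alpha = {fit['alpha']:.3f}, "
          f"median OR = {fit['median_or']:.2f}")
    print("rerun byte-identical:", manifest.checksums == rerun.checksums)
    print("-> the manifest's config hash and checksums make runs auditable;")
    print("   the same config always reproduces the same bytes.")
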