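"""Run the whole pipeline from one config and seed.

simulate -> call-se (both conditions) -> diff-se -> prioritize -> crc ->
enrich, with per-stage seeds derived from the global seed, all outputs as
deterministic TSV/JSON under the output directory, and a run manifest
echoing parameters and summary counts.

Equivalent shell command:  secircuit run --seed 1 --outdir out/
"""

import json
import tempfile

from secircuit import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as outdir:
    manifest = run_pipeline(PipelineConfig(seed=1), outdir)
    print(json.dumps(manifest["summary"], indent=1, sort_keys=True))
# candidates_lost_up_model equals the generator's planted candidate count;
# the representative CRC lists the planted clique members.
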