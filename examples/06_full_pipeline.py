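"""Run the whole pipeline from files, the way the CLI does.

Writes a simulated cohort to disk, then executes score -> survival -> DEG ->
variants -> spatial via run_pipeline and prints the manifest summary.
Equivalent shell session:

    tp53tme simulate --seed 3 --out cohort/
    tp53tme run --config pipeline.yaml
"""

import json
import tempfile
from pathlib import Path

from tp53tme import SimulationConfig, io, simulate_cohort, simulate_spatial
from tp53tme.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = SimulationConfig(n_samples=60, n_rois_per_group=4, seed=3)
    bundle = simulate_cohort(cfg)
    io.write_table(bundle["expression"], tmp / "expression.tsv")
    io.write_table(bundle["clinical"], tmp / "clinical.tsv")
    io.write_table(bundle["variants"], tmp / "variants.tsv", index=False)
    cells, masks = simulate_spatial(cfg)
    io.write_table(cells, tmp / "cells.csv", index=False)
    io.write_table(masks, tmp / "masks.csv", index=False)

    manifest = run_pipeline(PipelineConfig(
        expression=str(tmp / "expression.tsv"),
        clinical=str(tmp / "clinical.tsv"),
        variants=str(tmp / "variants.tsv"),
        cells=str(tmp / "cells.csv"),
        mask=str(tmp / "masks.csv"),
        out_dir=str(tmp / "out"),
    ))
    print(json.dumps(manifest["stages"], indent=2))
# Each stage reports status, timing and its headline number (log-rank p,
# DEG count, mutant count, boundary rank-sum p); outputs land as TSVs plus
# manifest.json in the configured directory.
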