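"""Umbrella pipeline: score -> classify -> survival / DEG / variants / spatial.

Each stage reads and writes plain TSV/CSV artifacts; a JSON manifest echoes
every parameter, the seed and per-stage status so a run is reproducible
from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as tio
from .diffexpr import deg_filter, two_group_test
from .scoring import ScoringConfig, classify_groups, tp53_score
from .signature import load_signature
from .spatial import assign_regions, grid_partition, region_abundance
from .survival import compare_groups
from .variants import assign_mutation_group, screen_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: Optional[str] = None
    clinical: Optional[str] = None
    variants: Optional[str] = None
    cells: Optional[str] = None
    mask: Optional[str] = None
    signature: str = "default"
    alpha: float = 0.25
    normalize: str = "none"
    cut: object = "median"
    fc_threshold: float = 1.5
    padj_threshold: float = 0.05
    depth_min: int = 30
    vaf_min: float = 0.01
    q_min: float = 10.0
    margin: float = 4.0
    roi_side: float = 1000.0
    n_blocks: int = 400
    center_phenotype: str = "Treg"
    gene: str = "TP53"
    seed: int = 0
    out_dir: str = "tp53tme_out"

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage whose inputs are configured; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": cfg.to_dict(), "stages": {}}
    scores = None

    def stage(name):
        def wrap(fn):
            t0 = _time.perf_counter()
            try:
                result = fn()
                manifest["stages"][name] = {
                    "status": "complete",
                    "seconds": round(_time.perf_counter() - t0, 3),
                    **(result or {}),
                }
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if cfg.expression:
        @stage("score")
        def _():
            nonlocal scores
            expr = tio.read_expression(cfg.expression)
            sig = load_signature(cfg.signature)
            table = tp53_score(expr, sig, ScoringConfig(alpha=cfg.alpha, normalize=cfg.normalize))
            scores = classify_groups(table, cfg.cut)
            tio.write_table(scores, out / "scores.tsv")
            return {"n_samples": len(scores)}

    if cfg.expression and cfg.clinical:
        @stage("survival")
        def _():
            clinical = tio.read_clinical(cfg.clinical)
            res = compare_groups(clinical, scores)
            for label, curve in res["curves"].items():
                tio.write_table(curve, out / f"km_{label}.tsv", index=False)
            return {"logrank_statistic": res["statistic"], "p_value": res["p_value"]}

    if cfg.expression:
        @stage("degs")
        def _():
            expr = tio.read_expression(cfg.expression)
            res = two_group_test(expr, scores["group"])
            degs = deg_filter(res, cfg.fc_threshold, cfg.padj_threshold)
            tio.write_table(degs, out / "degs.tsv")
            return {"n_degs": int(degs["is_deg"].sum())}

    if cfg.variants:
        @stage("variants")
        def _():
            var = tio.read_table(cfg.variants, index_col=None)
            screened = screen_table(var, cfg.depth_min, cfg.vaf_min, cfg.q_min)
            universe = (
                scores.index if scores is not None else pd.unique(var["sample_id"])
            )
            status = assign_mutation_group(screened, universe, gene=cfg.gene)
            tio.write_table(screened, out / "variants_screened.tsv", index=False)
            tio.write_table(status.to_frame(), out / "mutation_groups.tsv")
            return {"n_mutant": int((status == "mutant").sum())}

    if cfg.cells and cfg.mask:
        @stage("spatial")
        def _():
            cells = tio.read_table(cfg.cells, index_col=None)
            mask = tio.read_table(cfg.mask, index_col=None)
            grid = grid_partition(cfg.roi_side, cfg.n_blocks)
            annotated = assign_regions(cells, mask, grid)
            table, stat, p = region_abundance(annotated, cfg.center_phenotype, "boundary")
            tio.write_table(table, out / "region_abundance.tsv", index=False)
            return {"boundary_ranksum_statistic": stat, "p_value": p}

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
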