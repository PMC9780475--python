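"""Somatic variant screening and per-sample TP53 mutation status.

Screening thresholds (all strict "greater than"):
  total depth > 30, variant allele fraction > 1%, phred-like quality
  Q = -10*log10(P) > 10.
A sample is assigned to the mutant group iff it carries at least one passing
record in the gene of interest (optionally restricted to a position
allowlist emulating hotspot-site calling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    gene: str
    position: int
    ref: str
    alt: str
    total_depth: int
    variant_depth: int
    quality_q: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise VariantError("ref and alt alleles must be non-empty")
        if self.total_depth < 0 or self.variant_depth < 0:
            raise VariantError("depths must be non-negative")
        if self.variant_depth > self.total_depth:
            raise VariantError(
                f"variant depth {self.variant_depth} exceeds total depth {self.total_depth}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0 when the site has no coverage."""
        return 0.0 if self.total_depth == 0 else self.variant_depth / self.total_depth


def screen_variant(
    v: VariantRecord,
    depth_min: int = 30,
    vaf_min: float = 0.01,
    q_min: float = 10.0,
) -> tuple[bool, Optional[str]]:
    """Apply the screening rule; returns (passed, first_failed_criterion).

    Criteria are checked in order depth, vaf, quality, each with a strict
    inequality; a zero-depth site fails on depth before any VAF division.
    """
    if not v.total_depth > depth_min:
        return False, "depth"
    if not v.vaf > vaf_min:
        return False, "vaf"
    if not v.quality_q > q_min:
        return False, "quality"
    return True, None


def screen_table(
    variants: pd.DataFrame,
    depth_min: int = 30,
    vaf_min: float = 0.01,
    q_min: float = 10.0,
) -> pd.DataFrame:
    """Vector form of :func:`screen_variant` over a variant table.

    Adds ``vaf``, ``passed`` and ``fail_reason`` columns.
    """
    out = variants.copy()
    depth = out["total_depth"].to_numpy(dtype=float)
    vdepth = out["variant_depth"].to_numpy(dtype=float)
    if (vdepth > depth).any():
        raise VariantError("variant depth exceeds total depth in at least one record")
    out["vaf"] = np.divide(vdepth, depth, out=np.zeros_like(vdepth), where=depth > 0)
    reason = pd.Series([None] * len(out), index=out.index, dtype=object)
    fail_depth = ~(depth > depth_min)
    fail_vaf = ~fail_depth & ~(out["vaf"] > vaf_min)
    fail_q = ~fail_depth & ~fail_vaf.to_numpy() & ~(out["quality_q"] > q_min)
    reason[fail_depth] = "depth"
    reason[fail_vaf.to_numpy()] = "vaf"
    reason[fail_q.to_numpy()] = "quality"
    out["fail_reason"] = reason
    out["passed"] = reason.isna()
    return out


def assign_mutation_group(
    screened: pd.DataFrame,
    sample_universe: Sequence[str],
    gene: str = "TP53",
    position_allowlist: Optional[Iterable[int]] = None,
) -> pd.Series:
    """Per-sample mutant/wildtype status from screened variant records.

    A sample is ``mutant`` iff it has >= 1 passing record in ``gene``
    (optionally restricted to ``position_allowlist`` sites); every sample in
    ``sample_universe`` without one is ``wildtype``.  Variant records naming
    samples outside the universe are an error.
    """
    universe = pd.Index(sample_universe)
    if universe.has_duplicates:
        raise VariantError("duplicate sample ids in universe")
    unknown = sorted(set(screened["sample_id"]) - set(universe))
    if unknown:
        raise VariantError(f"variant records for samples outside the universe: {unknown}")
    hits = screened[screened["passed"] & (screened["gene"] == gene)]
    if position_allowlist is not None:
        hits = hits[hits["position"].isin(set(position_allowlist))]
    status = pd.Series("wildtype", index=universe, name="mutation_group")
    status[status.index.isin(hits["sample_id"])] = "mutant"
    return status
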