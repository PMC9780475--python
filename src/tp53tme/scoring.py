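"""Single-sample enrichment scoring and TP53 activity classification.

For each sample, genes are ranked by descending expression and a running-sum
enrichment score (ssGSEA-style) is computed for the induced and the repressed
signature sets.  The TP53 activity score is

    score = S_induce - S_repress

and samples are dichotomized into high/low activity groups (median split by
default).  A low score proxies TP53 inactivation.

The running sum walks genes from highest to lowest expression and accumulates

    ES = sum_i [ P_in^w(i) - P_out(i) ]

where ``P_in^w`` is the weighted fraction of set-member mass seen so far
(gene at rank r carries weight ``(N - r + 1)**alpha``, so the top gene gets
the largest weight) and ``P_out`` is the unweighted fraction of non-members.
At ``alpha = 0`` this reduces to the plain difference of the two empirical
CDFs summed over all rank positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signature import GeneSignature

logger = logging.getLogger(__name__)

TiePolicy = str  # "average_rank" | "stable_order"


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the running-sum score.

    alpha : rank-weight exponent; 0 gives the unweighted ECDF difference,
        0.25 is the default weighting.
    normalize : "none" keeps raw enrichment scores; "range" divides each
        direction's score vector by its (max - min) across samples before
        subtraction.
    tie_policy : how tied expression values are ranked ("average_rank" or
        "stable_order").
    """

    alpha: float = 0.25
    normalize: str = "none"
    tie_policy: TiePolicy = "average_rank"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ScoringError(f"alpha must be >= 0, got {self.alpha}")
        if self.normalize not in ("none", "range"):
            raise ScoringError(f"normalize must be 'none' or 'range', got {self.normalize!r}")
        if self.tie_policy not in ("average_rank", "stable_order"):
            raise ScoringError(f"unknown tie_policy {self.tie_policy!r}")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (genes x samples) for finiteness and unique ids."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ScoringError(f"duplicate gene ids: {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ScoringError(f"duplicate sample ids: {dups}")
    values = expr.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise ScoringError(
            f"non-finite expression value for gene {expr.index[gi]!r} "
            f"in sample {expr.columns[si]!r}"
        )
    return expr


def rank_transform(expr: pd.DataFrame, tie_policy: TiePolicy = "average_rank") -> pd.DataFrame:
    """Per-sample gene ranks by descending expression (rank 1 = highest).

    Under ``average_rank`` ties receive their average rank; under
    ``stable_order`` ties are broken by input gene order, yielding an exact
    permutation of 1..N in every sample.
    """
    validate_expression(expr)
    values = expr.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    ranks = np.empty_like(values)
    for j in range(n_samples):
        if tie_policy == "average_rank":
            ranks[:, j] = rankdata(-values[:, j], method="average")
        else:
            order = np.argsort(-values[:, j], kind="stable")
            ranks[order, j] = np.arange(1, n_genes + 1)
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def _es_from_ranks(
    ranks: np.ndarray, in_set: np.ndarray, alpha: float
) -> np.ndarray:
    """Running-sum ES for each column of a ranks matrix.

    ranks : (n_genes, n_samples) per-sample ranks, 1 = top.
    in_set : boolean (n_genes,) set-membership mask.
    """
    n_genes, n_samples = ranks.shape
    n_in = int(in_set.sum())
    n_out = n_genes - n_in
    es = np.empty(n_samples)
    for j in range(n_samples):
        order = np.argsort(ranks[:, j], kind="stable")
        sorted_r = ranks[order, j]
        mask = in_set[order]
        weights = (n_genes - sorted_r + 1.0) ** alpha
        w_in = np.where(mask, weights, 0.0)
        # tied ranks are evaluated as a group: each gene sees the cumulative
        # mass through the END of its tie group, so the walk order within a
        # tie cannot break symmetry
        group_end = np.searchsorted(sorted_r, sorted_r, side="right") - 1
        p_in = np.cumsum(w_in)[group_end] / w_in.sum()
        p_out = np.cumsum(~mask)[group_end] / n_out
        es[j] = float(np.sum(p_in - p_out))
    return es


def enrichment_score(
    ranked_sample: Union[Mapping[str, float], pd.Series],
    gene_set: Iterable[str],
    alpha: float = 0.25,
) -> float:
    """Running-sum enrichment score of ``gene_set`` in one ranked sample.

    ``ranked_sample`` maps gene symbol -> rank (1 = highest expression).

    Raises
    ------
    ScoringError
        If the set shares no genes with the rank universe, or covers it
        entirely (the non-member ECDF is then undefined).
    """
    if alpha < 0:
        raise ScoringError(f"alpha must be >= 0, got {alpha}")
    series = pd.Series(ranked_sample, dtype=float)
    genes = series.index
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in set(genes)]
    if not present:
        raise ScoringError(f"gene set disjoint from rank universe; missing: {sorted(gene_set)}")
    if len(present) == len(genes):
        raise ScoringError("gene set equals the whole universe; non-member ECDF undefined")
    in_set = np.asarray(pd.Index(genes).isin(present))
    return float(_es_from_ranks(series.to_numpy()[:, None], in_set, alpha)[0])


def tp53_score(
    expr: pd.DataFrame,
    sig: GeneSignature,
    cfg: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Per-sample TP53 activity scores (without group labels).

    Returns a DataFrame indexed by sample id with columns
    ``s_induce``, ``s_repress`` and ``score = s_induce - s_repress``.
    Signature genes absent from the matrix are dropped with a logged
    warning; an entirely absent direction is an error.
    """
    validate_expression(expr)
    universe = set(expr.index)
    missing = [g for g in sig.genes if g not in universe]
    if missing:
        logger.warning("signature genes absent from expression matrix: %s", ", ".join(missing))
    induced = [g for g in sig.induced if g in universe]
    repressed = [g for g in sig.repressed if g in universe]
    if not induced:
        raise ScoringError("no induced signature genes present in the expression matrix")
    if not repressed:
        raise ScoringError("no repressed signature genes present in the expression matrix")

    ranks = rank_transform(expr, cfg.tie_policy).to_numpy()
    genes = expr.index
    s_induce = _es_from_ranks(ranks, np.asarray(genes.isin(induced)), cfg.alpha)
    s_repress = _es_from_ranks(ranks, np.asarray(genes.isin(repressed)), cfg.alpha)
    if cfg.normalize == "range":
        for vec in (s_induce, s_repress):
            span = vec.max() - vec.min()
            if span > 0:
                vec /= span
    table = pd.DataFrame(
        {"s_induce": s_induce, "s_repress": s_repress},
        index=pd.Index(expr.columns, name="sample_id"),
    )
    table["score"] = table["s_induce"] - table["s_repress"]
    return table


def classify_groups(
    scores: pd.DataFrame, cut: Union[str, float] = "median"
) -> pd.DataFrame:
    """Assign high/low activity groups by thresholding the score.

    ``cut`` is either the string ``"median"`` or an explicit numeric
    cut-point; a sample is ``high`` iff its score is strictly greater than
    the cut-point.
    """
    if len(scores) < 2:
        raise ScoringError("need at least 2 samples to form groups")
    values = scores["score"].to_numpy(dtype=float)
    if isinstance(cut, str):
        if cut != "median":
            raise ScoringError(f"cut must be 'median' or a number, got {cut!r}")
        if np.all(values == values[0]):
            raise ScoringError(
                "all scores identical; median split degenerate — pass an explicit cut value"
            )
        cut_value = float(np.median(values))
    else:
        cut_value = float(cut)
    out = scores.copy()
    out["group"] = np.where(values > cut_value, "high", "low")
    return out
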