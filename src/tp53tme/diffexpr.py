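"""Differential expression between score groups at the published thresholds.

A desk-scale two-group stage: per-gene Welch t-test on log2(x + 1) values,
Benjamini-Hochberg adjustment, and the calling rule

    DEG  iff  p_adj < 0.05  and  |fold change| > 1.5

interpreted symmetrically on the ratio scale (FC > 1.5 or FC < 1/1.5, strict
inequalities).  The fold change is the ratio of group geometric means,
``test_group`` over the other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class DiffExprError(ValueError):
    pass


def two_group_test(
    expr: pd.DataFrame, groups: pd.Series, test_group: str = "high"
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(x+1) expression between two groups.

    Returns a DataFrame indexed by gene with columns ``fold_change``
    (2**(mean log difference), test_group over the other), ``log2_fc``
    and ``p_value``.  Genes with zero variance in both groups get p = 1
    when the means agree (and p = 0 for a zero-variance mean difference,
    where the t statistic is infinite).
    """
    groups = groups.reindex(expr.columns)
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise DiffExprError(f"expected exactly 2 group labels, got {list(labels)}")
    if test_group not in labels:
        raise DiffExprError(f"test_group {test_group!r} not among labels {list(labels)}")
    other = labels[labels != test_group][0]
    a = expr.loc[:, (groups == test_group).to_numpy()]
    b = expr.loc[:, (groups == other).to_numpy()]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DiffExprError("each group needs at least 2 samples")

    la = np.log2(a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(b.to_numpy(dtype=float) + 1.0)
    log2_fc = la.mean(axis=1) - lb.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    if degenerate.any():
        logger.info("%d genes with zero variance in both groups", int(degenerate.sum()))
        p[degenerate] = np.where(np.isclose(log2_fc[degenerate], 0.0), 1.0, 0.0)
    return pd.DataFrame(
        {"fold_change": 2.0 ** log2_fc, "log2_fc": log2_fc, "p_value": p},
        index=pd.Index(expr.index, name="gene_id"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffExprError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_filter(
    results: pd.DataFrame, fc_threshold: float = 1.5, padj_threshold: float = 0.05
) -> pd.DataFrame:
    """Apply the DEG calling rule; adds ``p_adj`` and ``is_deg`` columns.

    ``is_deg`` is true iff p_adj < padj_threshold and the fold change lies
    strictly outside [1/fc_threshold, fc_threshold].
    """
    if fc_threshold <= 0 or padj_threshold <= 0:
        raise DiffExprError("thresholds must be positive")
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    fc = out["fold_change"].to_numpy(dtype=float)
    out["is_deg"] = (out["p_adj"].to_numpy() < padj_threshold) & (
        (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    )
    return out
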