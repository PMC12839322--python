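"""Differential promoter methylation and expression, CIMP-H vs Non-CIMP.

Both omics are tested gene-wise with two-sided Welch t-tests — methylation
on promoter-average beta values, expression on TMM-normalized log2-CPM —
and corrected with Benjamini–Hochberg separately within each omic.  Genes
are then classified into five categories by combining the Δβ ≥ 0.2 and
|log2FC| ≥ 1.3 effect thresholds with significance of both adjusted
p-values: hyper-down, hyper-up, hypo-down, hypo-up, or not-significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Config
from .io import ValidationError

CATEGORIES = ("hyper-down", "hyper-up", "hypo-down", "hypo-up", "not-significant")

SIGNIFICANT_CATEGORIES = CATEGORIES[:4]


class AnalysisError(ValueError):
    """Analysis cannot proceed (e.g. a group with fewer than two samples)."""


def _split_groups(matrix: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = groups[groups.isin(["CIMP-H", "Non-CIMP"])]
    hi = groups.index[groups == "CIMP-H"]
    lo = groups.index[groups == "Non-CIMP"]
    for name, idx in (("CIMP-H", hi), ("Non-CIMP", lo)):
        if len(idx) < 2:
            raise AnalysisError(f"group {name} has {len(idx)} sample(s); need >= 2")
        missing = idx.difference(matrix.columns)
        if len(missing):
            raise AnalysisError(f"samples absent from matrix: {missing[:3].tolist()}")
    return matrix[hi].to_numpy(dtype=float), matrix[lo].to_numpy(dtype=float)


def _welch_two_group(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Row-wise group mean difference (CIMP-H − Non-CIMP) and Welch p."""
    a, b = _split_groups(matrix, groups)
    effect = a.mean(axis=1) - b.mean(axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: both groups constant -> equal means p=1, else p=0
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p = p.copy()
        p[degenerate] = np.where(effect[degenerate] == 0.0, 1.0, 0.0)
    return pd.DataFrame({"effect": effect, "p": p}, index=matrix.index)


def diff_methylation(promoter_avg: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene Δβ (difference of group-mean promoter-average betas) and
    two-sided Welch p-value."""
    res = _welch_two_group(promoter_avg, groups)
    return res.rename(columns={"effect": "delta_beta", "p": "meth_p"})


def diff_expression(log2cpm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene log2 fold change (difference of group-mean log2-CPM) and
    two-sided Welch p-value."""
    res = _welch_two_group(log2cpm, groups)
    return res.rename(columns={"effect": "log2fc", "p": "expr_p"})


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    NaN entries are excluded from the procedure and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        bad = p[mask][(p[mask] < 0) | (p[mask] > 1)][0]
        raise ValidationError(f"p-value outside [0, 1]: {bad}")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify_gene(
    delta_beta: float,
    log2fc: float,
    meth_adj_p: float,
    expr_adj_p: float,
    cfg: Config,
) -> str:
    """Five-way category for one gene.

    A significant call needs both adjusted p-values below alpha AND both
    effect sizes past their thresholds; the sign pattern picks the class.
    """
    if (
        meth_adj_p < cfg.alpha
        and expr_adj_p < cfg.alpha
        and abs(delta_beta) >= cfg.delta_beta_min
        and abs(log2fc) >= cfg.abs_log2fc_min
    ):
        meth = "hyper" if delta_beta > 0 else "hypo"
        expr = "up" if log2fc > 0 else "down"
        return f"{meth}-{expr}"
    return "not-significant"


def run_differential(
    promoter_avg: pd.DataFrame,
    log2cpm: pd.DataFrame,
    groups: pd.Series,
    cfg: Config,
) -> pd.DataFrame:
    """Full differential table for genes present in both omics.

    Columns: delta_beta, meth_p, meth_adj_p, log2fc, expr_p, expr_adj_p,
    category.  BH correction is applied separately within each omic across
    all tested genes.
    """
    genes = promoter_avg.index.intersection(log2cpm.index)
    if genes.empty:
        raise AnalysisError("no gene is present in both omics")
    meth = diff_methylation(promoter_avg.loc[genes], groups)
    expr = diff_expression(log2cpm.loc[genes], groups)
    rec = pd.concat([meth, expr], axis=1)
    rec["meth_adj_p"] = bh_adjust(rec["meth_p"])
    rec["expr_adj_p"] = bh_adjust(rec["expr_p"])
    rec["category"] = [
        classify_gene(db, fc, mp, ep, cfg)
        for db, fc, mp, ep in zip(
            rec["delta_beta"], rec["log2fc"], rec["meth_adj_p"], rec["expr_adj_p"]
        )
    ]
    cols = ["delta_beta", "meth_p", "meth_adj_p", "log2fc", "expr_p",
            "expr_adj_p", "category"]
    return rec[cols].rename_axis("gene")
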