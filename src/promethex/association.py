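"""Promoter methylation–expression association scoring.

Six scorers quantify, per candidate gene, how well promoter methylation
explains expression across the pooled CIMP-H and Non-CIMP samples.  The
Spearman family correlates log2-CPM with (i) each promoter CpG separately,
averaging the signed correlations ("single"), (ii) the promoter-average
beta ("average"), or (iii) the fraction of methylated CpGs (β ≥ 0.3,
"ratio").  The regression family fits ordinary least squares with the same
three predictor choices — all promoter CpG betas jointly for "single" —
and scores the adjusted R², with the overall F-test p-value guarding
significance.  Adjusted R² penalizes predictor count, making promoters of
different CpG sizes comparable.

Selection follows the published thresholds: |ρ| > 0.4 with BH-adjusted
p < 0.05 for Spearman scorers, adjusted R² > 0.5 with model p < 0.05 for
regression scorers.  ``compare_methods`` reproduces the cross-method
comparison: Kruskal–Wallis across each family's score distributions,
per-gene argmax counts (ties credited to every tied method), and the
selected-set overlap matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .config import Config
from .differential import bh_adjust

log = logging.getLogger(__name__)

SPEARMAN_METHODS = ("spearman-single", "spearman-average", "spearman-ratio")
REGRESSION_METHODS = ("regression-single", "regression-average", "regression-ratio")
METHODS = SPEARMAN_METHODS + REGRESSION_METHODS

#: smallest p-value entering Fisher's combination (guards log(0))
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-aware Spearman correlation with t-approximation p-value.

    Returns ``(nan, nan)`` when either argument has zero variance.
    |ρ| = 1 yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError(f"need at least 5 observations, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        log.debug("spearman_rho: zero-variance input, score NA")
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.array_equal(rx, ry):
        return 1.0, 0.0
    if np.array_equal(rx, len(rx) + 1 - ry):
        return -1.0, 0.0
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    return float(rho), float(p)


def fisher_combine(pvals) -> float:
    """Fisher's chi-square combination of independent p-values."""
    p = np.clip(np.asarray(pvals, dtype=float), _P_FLOOR, 1.0)
    statistic = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(statistic, 2 * p.size))


@dataclass
class RegressionFit:
    adj_r2: float
    model_p: float
    k_eff: int
    status: str  # "ok", "underdetermined", "insufficient-df"


def fit_promoter_regression(predictors: np.ndarray, response: np.ndarray) -> RegressionFit:
    """OLS of expression on promoter methylation predictors.

    Rank-deficient predictor sets are reduced to an independent column
    basis via pivoted QR; ``k_eff`` is the effective rank.  Requires
    n ≥ k + 3 (else "underdetermined") and at least 3 residual degrees of
    freedom after reduction (else "insufficient-df").  The score is
    adjusted R² = 1 − (1−R²)(n−1)/(n−k_eff−1); the p-value is the upper
    tail of F(k_eff, n−k_eff−1).
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and predictors.ndim == 1:
        X = X.T
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match predictor rows")
    if np.ptp(y) == 0.0:
        raise ValueError("zero-variance response")
    if n < k + 3:
        return RegressionFit(np.nan, np.nan, k, "underdetermined")
    # independent column basis of the centered design
    Xc = X - X.mean(axis=0)
    _, r, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(np.atleast_2d(r)))
    if diag.size == 0 or diag[0] == 0.0:
        k_eff, cols = 0, []
    else:
        tol = diag[0] * max(n, k) * np.finfo(float).eps
        k_eff = int(np.sum(diag > tol))
        cols = piv[:k_eff]
    if k_eff == 0:
        return RegressionFit(0.0, 1.0, 0, "ok")
    df_resid = n - k_eff - 1
    if df_resid < 3:
        return RegressionFit(np.nan, np.nan, k_eff, "insufficient-df")
    fit = sm.OLS(y, sm.add_constant(X[:, cols])).fit()
    r2 = float(fit.rsquared)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    if 1.0 - r2 <= 1e-14:
        return RegressionFit(1.0, 0.0, k_eff, "ok")
    f_stat = (r2 / k_eff) / ((1.0 - r2) / df_resid)
    model_p = float(stats.f.sf(f_stat, k_eff, df_resid))
    return RegressionFit(adj_r2, model_p, k_eff, "ok")


# ---------------------------------------------------------------------------
# per-gene scorers
# ---------------------------------------------------------------------------

def score_spearman(
    probe_betas: pd.DataFrame,
    summaries: dict[str, pd.Series],
    expression: pd.Series,
    variant: str,
) -> dict:
    """One gene's Spearman score.

    ``probe_betas``: promoter probes × samples; ``summaries``: the gene's
    "average" and "ratio" rows; ``expression``: the gene's log2-CPM.
    "single" averages signed per-CpG correlations and combines the
    per-CpG p-values with Fisher's method; "average"/"ratio" correlate the
    one summary directly.
    """
    y = expression.to_numpy(dtype=float)
    n = y.size
    k = probe_betas.shape[0]
    if variant == "single":
        rhos, ps = [], []
        for _, row in probe_betas.iterrows():
            rho, p = spearman_rho(row.to_numpy(dtype=float), y)
            if np.isfinite(rho):
                rhos.append(rho)
                ps.append(p)
        if not rhos:
            return dict(score=np.nan, p=np.nan, n_cpgs=k, n_samples=n, status="degenerate")
        return dict(score=float(np.mean(rhos)), p=fisher_combine(ps),
                    n_cpgs=k, n_samples=n, status="ok")
    if variant not in ("average", "ratio"):
        raise ValueError(f"unknown variant {variant!r}")
    rho, p = spearman_rho(summaries[variant].to_numpy(dtype=float), y)
    status = "ok" if np.isfinite(rho) else "degenerate"
    return dict(score=rho, p=p, n_cpgs=k, n_samples=n, status=status)


def score_regression(
    probe_betas: pd.DataFrame,
    summaries: dict[str, pd.Series],
    expression: pd.Series,
    variant: str,
) -> dict:
    """One gene's regression score (adjusted R² and model F p-value)."""
    y = expression.to_numpy(dtype=float)
    n = y.size
    k = probe_betas.shape[0]
    if variant == "single":
        X = probe_betas.to_numpy(dtype=float).T
    elif variant in ("average", "ratio"):
        X = summaries[variant].to_numpy(dtype=float)[:, None]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    fit = fit_promoter_regression(X, y)
    return dict(score=fit.adj_r2, p=fit.model_p, n_cpgs=k, n_samples=n,
                status=fit.status)


def score_all_methods(
    betas: pd.DataFrame,
    promoter_map: dict[str, list[str]],
    promoter_avg: pd.DataFrame,
    promoter_ratio: pd.DataFrame,
    log2cpm: pd.DataFrame,
    candidate_genes,
    samples=None,
) -> pd.DataFrame:
    """Long-format score table for every candidate gene × six methods.

    BH adjustment runs across genes within each method (NA scores are
    excluded from the correction and stay NA).
    """
    if samples is None:
        samples = log2cpm.columns
    samples = pd.Index(samples)
    rows = []
    for gene in candidate_genes:
        if gene not in promoter_map or gene not in log2cpm.index:
            continue
        probes = promoter_map[gene]
        block = betas.loc[probes, samples]
        summaries = {
            "average": promoter_avg.loc[gene, samples],
            "ratio": promoter_ratio.loc[gene, samples],
        }
        y = log2cpm.loc[gene, samples]
        for family, scorer in (("spearman", score_spearman),
                               ("regression", score_regression)):
            for variant in ("single", "average", "ratio"):
                rec = scorer(block, summaries, y, variant)
                rec.update(gene=gene, method=f"{family}-{variant}")
                rows.append(rec)
    scores = pd.DataFrame(
        rows, columns=["gene", "method", "score", "p", "n_cpgs", "n_samples",
                       "status"]
    )
    scores["adj_p"] = np.nan
    for method in METHODS:
        idx = scores.index[scores["method"] == method]
        if len(idx):
            scores.loc[idx, "adj_p"] = bh_adjust(scores.loc[idx, "p"])
    return scores


# ---------------------------------------------------------------------------
# selection, ranking, comparison
# ---------------------------------------------------------------------------

def select_genes(scores: pd.DataFrame, cfg: Config) -> pd.DataFrame:
    """Apply the per-family selection rules and rank the selected genes.

    Spearman: |ρ| strictly above ``spearman_abs_min`` and adjusted p below
    alpha.  Regression: adjusted R² strictly above ``adj_r2_min`` and model
    p below alpha.  Rank is 1-based among selected genes within a method,
    descending |ρ| / adjusted R², ties broken lexicographically by gene.
    """
    out = scores.copy()
    is_spear = out["method"].isin(SPEARMAN_METHODS)
    score = out["score"]
    with np.errstate(invalid="ignore"):
        sel_spear = is_spear & (score.abs() > cfg.spearman_abs_min) & (
            out["adj_p"] < cfg.alpha)
        sel_regr = ~is_spear & (score > cfg.adj_r2_min) & (out["p"] < cfg.alpha)
    out["selected"] = (sel_spear | sel_regr).fillna(False)
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    for method in METHODS:
        sel = out.index[(out["method"] == method) & out["selected"]]
        if not len(sel):
            continue
        key = out.loc[sel, "score"].abs() if method in SPEARMAN_METHODS \
            else out.loc[sel, "score"]
        order = sorted(sel, key=lambda i: (-key[i], out.loc[i, "gene"]))
        out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out


@dataclass
class MethodComparison:
    """Cross-method comparison within the two scorer families."""

    kw: dict[str, tuple[float, float]]       # family → (H, p)
    argmax_counts: dict[str, int]            # method → #genes at family max
    overlap: pd.DataFrame                    # gene × method selected matrix

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method in METHODS:
            family = "spearman" if method in SPEARMAN_METHODS else "regression"
            h, p = self.kw[family]
            rows.append({"method": method, "family": family, "kw_H": h,
                         "kw_p": p, "argmax_count": self.argmax_counts[method],
                         "n_selected": int(self.overlap[method].sum())
                         if method in self.overlap.columns else 0})
        return pd.DataFrame(rows)


def _family_scale(scores: pd.DataFrame, methods) -> pd.DataFrame:
    """gene × method matrix on the family's comparison scale."""
    sub = scores[scores["method"].isin(methods)]
    wide = sub.pivot(index="gene", columns="method", values="score")
    if set(methods) <= set(SPEARMAN_METHODS):
        wide = wide.abs()
    return wide.reindex(columns=list(methods))


def compare_methods(scores: pd.DataFrame, tie_tol: float = 1e-12) -> MethodComparison:
    """Kruskal–Wallis per family, per-gene argmax counts, overlap matrix.

    The Spearman family is compared on |ρ| and the regression family on
    adjusted R².  A gene credits every method within ``tie_tol`` of its
    family maximum.
    """
    if scores.empty:
        raise ValueError("empty score table")
    kw: dict[str, tuple[float, float]] = {}
    argmax_counts = {m: 0 for m in METHODS}
    for family, methods in (("spearman", SPEARMAN_METHODS),
                            ("regression", REGRESSION_METHODS)):
        wide = _family_scale(scores, methods)
        groups = [wide[m].dropna().to_numpy() for m in methods]
        groups = [g for g in groups if g.size]
        if len(groups) < 2:
            raise ValueError(f"family {family!r} has fewer than two scored methods")
        try:
            h, p = stats.kruskal(*groups)
        except ValueError:  # all scores identical
            h, p = 0.0, 1.0
        if not (np.isfinite(h) and np.isfinite(p)):  # degenerate ties
            h, p = 0.0, 1.0
        kw[family] = (float(h), float(p))
        for _, row in wide.iterrows():
            vals = row.dropna()
            if vals.empty:
                continue
            top = vals.max()
            for m in vals.index[vals >= top - tie_tol]:
                argmax_counts[m] += 1
    sel = scores.pivot(index="gene", columns="method", values="selected")
    overlap = sel.fillna(False).astype(bool).reindex(columns=list(METHODS))
    return MethodComparison(kw=kw, argmax_counts=argmax_counts, overlap=overlap)
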