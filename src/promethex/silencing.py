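"""Epigenetic silencing calls and the perc.diff consistency metric.

Implements an external, independently derived silencing definition used
to corroborate the association scorers.  A probe is epigenetically
silenced when (i) at least 1% of samples are methylated for it (beta
strictly above 0.3), (ii) the methylated samples' mean expression z-score
is below −1.65, and (iii) a one-sided Welch test (methylated < rest) is
significant at FDR < 0.001 (BH across all probes tested).  A gene is
silenced when a strict majority of its promoter probes are; a sample is
silenced for such a gene when a strict majority of the gene's promoter
probes are methylated in it.  perc.diff is the percentage of CIMP-H
samples silenced minus the same percentage among Non-CIMP — genes truly
repressed by methylation should sit in the upper tail of that metric.

Expression z-scores are standardized per gene over all samples; the
one-sided test and the per-sample call are package-level constructions
where the external definition is silent, isolated here so alternatives
can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config
from .differential import bh_adjust

METH_BETA_STRICT = 0.3  # "beta value above 0.3" — strictly greater


def _zscore(vec: np.ndarray) -> np.ndarray:
    sd = vec.std(ddof=1)
    if sd == 0:
        return np.zeros_like(vec)
    return (vec - vec.mean()) / sd


def probe_silencing_stats(
    probe_betas: np.ndarray, expr_z: np.ndarray, cfg: Config
) -> dict:
    """Per-probe silencing evidence before FDR correction.

    Returns the methylated-sample mask, the mean z of the methylated
    group, and the raw one-sided Welch p (methylated < unmethylated).
    ``p`` is NaN when there is no contrast (all or no samples methylated).
    """
    n = probe_betas.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    meth = probe_betas > METH_BETA_STRICT
    n_meth = int(meth.sum())
    rec = dict(n_meth=n_meth, meth_mask=meth, mean_z=np.nan, p=np.nan)
    if n_meth == 0 or n_meth == n:
        return rec
    rec["mean_z"] = float(expr_z[meth].mean())
    if n_meth >= 2 and (n - n_meth) >= 2:
        res = stats.ttest_ind(expr_z[meth], expr_z[~meth], equal_var=False,
                              alternative="less")
        rec["p"] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return rec


def call_probe_silencing(
    probe_betas: np.ndarray,
    expr_z: np.ndarray,
    adj_p: float,
    cfg: Config,
) -> bool:
    """Final probe call given its BH-adjusted p-value."""
    rec = probe_silencing_stats(probe_betas, expr_z, cfg)
    n = probe_betas.size
    frac = rec["n_meth"] / n
    return bool(
        frac >= cfg.silencing_sample_frac
        and np.isfinite(rec["mean_z"])
        and rec["mean_z"] < cfg.silencing_z_max
        and np.isfinite(adj_p)
        and adj_p < cfg.silencing_alpha
    )


@dataclass
class SilencingCall:
    gene: str
    probe_silenced: dict[str, bool]
    gene_silenced: bool
    sample_silenced: pd.Series  # per sample, bool
    pct_cimp_h: float
    pct_non_cimp: float
    perc_diff: float


def call_gene_silencing(
    betas: pd.DataFrame,
    promoter_map: dict[str, list[str]],
    log2cpm: pd.DataFrame,
    groups: pd.Series,
    cfg: Config,
) -> pd.DataFrame:
    """Silencing calls and perc.diff for every mapped gene.

    BH correction of the probe-level one-sided tests runs across all
    probes of all genes jointly.  Percentages are over the CIMP-H and
    Non-CIMP samples in ``groups``.
    """
    samples = betas.columns
    genes = [g for g in promoter_map if g in log2cpm.index]
    # first pass: raw stats for every (gene, probe)
    stats_by_gene: dict[str, list] = {}
    raw_ps = []
    for gene in genes:
        z = _zscore(log2cpm.loc[gene, samples].to_numpy(dtype=float))
        recs = []
        for pid in promoter_map[gene]:
            rec = probe_silencing_stats(
                betas.loc[pid, samples].to_numpy(dtype=float), z, cfg
            )
            rec["probe_id"] = pid
            raw_ps.append(rec["p"])
            recs.append(rec)
        stats_by_gene[gene] = recs
    adj = bh_adjust(raw_ps) if raw_ps else np.array([])
    # second pass: apply the three clauses and aggregate
    hi = groups.index[groups == "CIMP-H"].intersection(samples)
    lo = groups.index[groups == "Non-CIMP"].intersection(samples)
    pos = 0
    rows = []
    n_samples = len(samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    for gene in genes:
        recs = stats_by_gene[gene]
        silenced_flags = []
        meth_count = np.zeros(n_samples, dtype=int)
        for rec in recs:
            frac = rec["n_meth"] / n_samples
            flag = bool(
                frac >= cfg.silencing_sample_frac
                and np.isfinite(rec["mean_z"])
                and rec["mean_z"] < cfg.silencing_z_max
                and np.isfinite(adj[pos])
                and adj[pos] < cfg.silencing_alpha
            )
            silenced_flags.append(flag)
            meth_count += rec["meth_mask"].astype(int)
            pos += 1
        n_probes = len(recs)
        gene_silenced = sum(silenced_flags) > n_probes / 2
        if gene_silenced:
            sample_silenced = meth_count > n_probes / 2
        else:
            sample_silenced = np.zeros(n_samples, dtype=bool)
        sil = pd.Series(sample_silenced, index=samples)
        pct_hi = 100.0 * sil[hi].mean() if len(hi) else np.nan
        pct_lo = 100.0 * sil[lo].mean() if len(lo) else np.nan
        rows.append(
            {
                "gene": gene,
                "n_probes": n_probes,
                "n_probes_silenced": int(sum(silenced_flags)),
                "gene_silenced": gene_silenced,
                "pct_cimp_h": pct_hi,
                "pct_non_cimp": pct_lo,
                "perc_diff": pct_hi - pct_lo,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class ConsistencyReport:
    q3: float
    fraction_above_q3: float        # NaN when the identified set is empty
    overall_summary: dict[str, float] = field(default_factory=dict)
    identified_summary: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"statistic": "q3_overall", "value": self.q3},
                {"statistic": "fraction_identified_above_q3",
                 "value": self.fraction_above_q3}]
        for name, summ in (("overall", self.overall_summary),
                           ("identified", self.identified_summary)):
            for stat, val in summ.items():
                rows.append({"statistic": f"{name}_{stat}", "value": val})
        return pd.DataFrame(rows)


def _five_number(vals: np.ndarray) -> dict[str, float]:
    if vals.size == 0:
        return {k: np.nan for k in ("min", "q1", "median", "q3", "max")}
    return {
        "min": float(np.min(vals)),
        "q1": float(np.percentile(vals, 25)),
        "median": float(np.median(vals)),
        "q3": float(np.percentile(vals, 75)),
        "max": float(np.max(vals)),
    }


def quartile_consistency(perc_diffs: pd.Series, identified) -> ConsistencyReport:
    """Where do the identified genes sit in the overall perc.diff
    distribution?

    Reports the overall upper quartile (Q3), the fraction of identified
    genes at or above it, and five-number summaries of both distributions.
    """
    identified = [g for g in identified]
    unknown = set(identified) - set(perc_diffs.index)
    if unknown:
        raise ValueError(f"identified gene(s) without silencing calls: "
                         f"{sorted(unknown)[:3]}")
    overall = perc_diffs.to_numpy(dtype=float)
    q3 = float(np.percentile(overall, 75))
    ident_vals = perc_diffs.loc[identified].to_numpy(dtype=float)
    frac = float(np.mean(ident_vals >= q3)) if ident_vals.size else float("nan")
    return ConsistencyReport(
        q3=q3,
        fraction_above_q3=frac,
        overall_summary=_five_number(overall),
        identified_summary=_five_number(ident_vals),
    )
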