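"""Probe filtering, promoter mapping, promoter summarization and TMM.

Filtering removes sex-chromosome probes (sex-specific methylation bias),
SNP-overlapping probes (sequence variability under the probe), and probes
with any missing value.  Promoter membership is taken from the manifest:
a probe belongs to a gene's promoter when annotated TSS1500 or TSS200 for
that gene, or when flagged promoter-associated — the manifest's TSS1500
label covers only 200–1500 bp upstream, so the union realizes "within
1500 bp of the TSS".

Counts are normalized by the trimmed mean of M-values (TMM): per-sample
log2 scaling factors from doubly-trimmed, precision-weighted gene-wise
log-ratios against a reference library, rescaled to geometric mean one,
followed by log2 counts-per-million with a small prior count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import BetaMatrix, CountMatrix, ProbeAnnotation, ValidationError

SEX_CHROMS = frozenset({"X", "Y"})

#: promoter region labels in the 450K manifest
PROMOTER_TSS_GROUPS = frozenset({"TSS1500", "TSS200"})


class NormalizationError(ValueError):
    """A library cannot be TMM-normalized against the reference."""


@dataclass
class FilterReport:
    """Counts of probes removed per reason (a probe may hit several reasons
    but is removed once)."""

    n_input: int
    n_sex_chrom: int
    n_snp_overlap: int
    n_missing: int
    n_removed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["sex_chromosome", "snp_overlap", "missing_values",
                           "total_removed", "kept"],
                "n": [self.n_sex_chrom, self.n_snp_overlap, self.n_missing,
                      self.n_removed, self.n_kept],
            }
        )


def filter_probes(
    annot: ProbeAnnotation, betas: BetaMatrix
) -> tuple[BetaMatrix, FilterReport]:
    """Drop sex-chromosome, SNP-overlapping and missing-value probes."""
    missing_annot = betas.probe_ids.difference(annot.probe_ids)
    if len(missing_annot):
        raise ValidationError(
            f"{len(missing_annot)} beta row(s) lack annotation, "
            f"e.g. {missing_annot[:3].tolist()}"
        )
    sub = annot.frame.loc[betas.probe_ids]
    on_sex = sub["chrom"].isin(SEX_CHROMS).to_numpy()
    snp = sub["snp_overlap"].to_numpy(dtype=bool)
    has_na = betas.values.isna().any(axis=1).to_numpy()
    removed = on_sex | snp | has_na
    report = FilterReport(
        n_input=len(betas.probe_ids),
        n_sex_chrom=int(on_sex.sum()),
        n_snp_overlap=int(snp.sum()),
        n_missing=int(has_na.sum()),
        n_removed=int(removed.sum()),
    )
    kept = BetaMatrix(betas.values.loc[~removed], n_clamped=betas.n_clamped)
    return kept, report


def build_promoter_map(
    annot: ProbeAnnotation,
    kept_probes,
    tss_groups: frozenset[str] = PROMOTER_TSS_GROUPS,
) -> dict[str, list[str]]:
    """gene symbol → ordered list of promoter probe ids.

    A probe maps to gene G when its manifest TSS group for G is promoter
    (TSS1500/TSS200) or the probe is promoter-associated and lists G.
    Genes without surviving promoter probes are absent.
    """
    kept = set(kept_probes)
    unknown = kept - set(annot.probe_ids)
    if unknown:
        raise ValidationError(f"kept probes not in annotation: {sorted(unknown)[:3]}")
    promoter_map: dict[str, list[str]] = {}
    for pid, genes, groups, prom_assoc in zip(
        annot.frame.index,
        annot.frame["genes"],
        annot.frame["tss_groups"],
        annot.frame["promoter_associated"],
    ):
        if pid not in kept:
            continue
        seen: set[str] = set()
        for gene, group in zip(genes, groups):
            if gene in seen:
                continue
            if group in tss_groups or prom_assoc:
                promoter_map.setdefault(gene, []).append(pid)
                seen.add(gene)
    return promoter_map


def summarize_promoter(
    betas: BetaMatrix,
    promoter_map: dict[str, list[str]],
    metric: str,
    beta_min: float = 0.3,
) -> pd.DataFrame:
    """Per-gene, per-sample promoter methylation summary.

    ``metric="average"``: arithmetic mean beta over the promoter probes.
    ``metric="ratio"``: fraction of promoter CpGs with beta >= ``beta_min``
    (a boundary beta counts as methylated).
    """
    if metric not in ("average", "ratio"):
        raise ValueError(f"metric must be 'average' or 'ratio', got {metric!r}")
    rows = {}
    for gene, probes in promoter_map.items():
        if not probes:
            continue
        block = betas.values.loc[probes].to_numpy()
        if metric == "average":
            rows[gene] = block.mean(axis=0)
        else:
            rows[gene] = (block >= beta_min).mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=betas.sample_ids).rename_axis("gene")


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

@dataclass
class NormalizedExpression:
    """TMM factors and log2 counts-per-million."""

    tmm_factors: pd.Series  # per-sample, geometric mean 1
    log2cpm: pd.DataFrame   # gene × sample

    @property
    def gene_ids(self) -> pd.Index:
        return self.log2cpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.log2cpm.columns


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 scaling factor of one library against the reference.

    Gene-wise M (log2 proportion ratio) and A (mean log2 abundance) are
    computed over genes positive in both libraries, doubly trimmed by rank
    (``trim_m`` each tail on M, ``trim_a`` on A), and averaged with inverse
    delta-method variance weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * (np.log2(obs / lib_obs) + np.log2(ref / lib_ref))
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0:
        raise NormalizationError("no gene is positive in both libraries")
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_normalize(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizedExpression:
    """TMM scaling factors plus log2-CPM.

    The reference library is the one whose 75th-percentile count proportion
    is closest to the mean of that statistic across libraries.  Factors are
    rescaled so their geometric mean is one.  log2-CPM uses prior counts
    0.5 (numerator) and 1.0 (effective library size).
    """
    x = counts.values.to_numpy(dtype=float)
    libs = x.sum(axis=0)
    if x.shape[1] < 2:
        raise NormalizationError("TMM needs at least two samples")
    f75 = np.array([np.quantile(x[:, j] / libs[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        try:
            log_factors[j] = _tmm_pair_factor(
                x[:, j], x[:, ref_idx], libs[j], libs[ref_idx], trim_m, trim_a
            )
        except NormalizationError as exc:
            raise NormalizationError(
                f"sample {counts.sample_ids[j]!r}: {exc}"
            ) from None
    factors = 2.0 ** (log_factors - log_factors.mean())
    eff_lib = libs * factors
    log2cpm = np.log2((x + 0.5) / (eff_lib + 1.0) * 1e6)
    return NormalizedExpression(
        tmm_factors=pd.Series(factors, index=counts.sample_ids, name="tmm_factor"),
        log2cpm=pd.DataFrame(log2cpm, index=counts.gene_ids,
                             columns=counts.sample_ids),
    )
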