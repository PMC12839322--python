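"""End-to-end model: promoter methylation explaining gene expression.

:class:`PromoterMethylationModel` bundles the four inputs of a cohort
analysis (probe annotation, beta matrix, raw counts, sample sheet) with a
:class:`~promethex.config.Config`; :meth:`~PromoterMethylationModel.fit`
runs the whole workflow — probe filtering, promoter mapping and
summarization, TMM normalization, CIMP stratification (sample-sheet
labels when present, otherwise the standardized CIMP-index), integrated
differential methylation/expression, the six association scorers with
selection and cross-method comparison, and the external-consistency
silencing metric — returning a :class:`PromoterMethylationResults` that
carries every intermediate table plus a ``summary()``.

The "identified" gene set used for the silencing consistency check is the
selection of the single-CpG-predictors regression, the scorer the study
design favors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import association, cimp, differential, preprocess, silencing
from .config import Config
from .io import BetaMatrix, CountMatrix, ProbeAnnotation, SampleSheet
from .preprocess import FilterReport, NormalizedExpression


class PromoterMethylationModel:
    """Joint promoter-methylation / expression analysis of one cohort."""

    def __init__(
        self,
        annot: ProbeAnnotation,
        betas: BetaMatrix,
        counts: CountMatrix,
        samples: SampleSheet,
        config: Config | None = None,
    ) -> None:
        self.annot = annot
        self.betas = betas
        self.counts = counts
        self.samples = samples
        self.config = config or Config()
        common = betas.sample_ids.intersection(counts.sample_ids).intersection(
            samples.sample_ids
        )
        if len(common) < 4:
            raise ValueError(
                f"only {len(common)} sample(s) shared by betas, counts and "
                "sample sheet; need >= 4"
            )
        # preserve beta-matrix column order
        self.sample_ids = betas.sample_ids[betas.sample_ids.isin(common)]

    @classmethod
    def from_cohort(cls, cohort, config: Config | None = None
                    ) -> "PromoterMethylationModel":
        """Build from a :class:`~promethex.simulate.Cohort`."""
        return cls(cohort.annot, cohort.betas, cohort.counts, cohort.samples,
                   config=config)

    def fit(self) -> "PromoterMethylationResults":
        cfg = self.config
        betas = BetaMatrix(self.betas.values[self.sample_ids],
                           n_clamped=self.betas.n_clamped)
        counts = CountMatrix(self.counts.values[self.sample_ids])

        kept, filter_report = preprocess.filter_probes(self.annot, betas)
        promoter_map = preprocess.build_promoter_map(self.annot, kept.probe_ids)
        promoter_avg = preprocess.summarize_promoter(kept, promoter_map, "average")
        promoter_ratio = preprocess.summarize_promoter(
            kept, promoter_map, "ratio", beta_min=cfg.meth_cpg_beta_min
        )
        norm = preprocess.tmm_normalize(counts)

        cimp_records = None
        if self.samples.has_labels():
            groups = self.samples.analysis_groups()
            groups = groups[groups.index.isin(self.sample_ids)]
        else:
            cimp_records = cimp.assign_cimp_class(
                cimp.cimp_index(kept, cimp.island_map(self.annot),
                                beta_min=cfg.meth_cpg_beta_min),
                hi=cfg.cimp_index_hi, lo=cfg.cimp_index_lo,
            )
            assigned = cimp_records["assigned_class"]
            groups = assigned[assigned.isin(["CIMP-H", "Non-CIMP"])]
        analysis_samples = self.sample_ids[self.sample_ids.isin(groups.index)]
        groups = groups.loc[analysis_samples]

        diff = differential.run_differential(
            promoter_avg[analysis_samples], norm.log2cpm[analysis_samples],
            groups, cfg,
        )
        candidates = diff.index[
            diff["category"].isin(differential.SIGNIFICANT_CATEGORIES)
        ]
        scores = association.score_all_methods(
            kept.values, promoter_map, promoter_avg, promoter_ratio,
            norm.log2cpm, candidates, samples=analysis_samples,
        )
        scores = association.select_genes(scores, cfg)
        comparison = association.compare_methods(scores) if len(scores) else None

        silencing_calls = silencing.call_gene_silencing(
            kept.values[analysis_samples], promoter_map,
            norm.log2cpm[analysis_samples], groups, cfg,
        )
        identified = scores.loc[
            (scores["method"] == "regression-single") & scores["selected"], "gene"
        ].tolist()
        identified = [g for g in identified if g in silencing_calls.index]
        consistency = silencing.quartile_consistency(
            silencing_calls["perc_diff"], identified
        ) if len(silencing_calls) else None

        return PromoterMethylationResults(
            model=self,
            filter_report=filter_report,
            promoter_map=promoter_map,
            promoter_avg=promoter_avg,
            promoter_ratio=promoter_ratio,
            normalized=norm,
            cimp_records=cimp_records,
            groups=groups,
            differential=diff,
            scores=scores,
            comparison=comparison,
            silencing_calls=silencing_calls,
            consistency=consistency,
        )


@dataclass
class PromoterMethylationResults:
    """Fitted-pipeline results with every intermediate table."""

    model: PromoterMethylationModel
    filter_report: FilterReport
    promoter_map: dict[str, list[str]]
    promoter_avg: pd.DataFrame
    promoter_ratio: pd.DataFrame
    normalized: NormalizedExpression
    cimp_records: Optional[pd.DataFrame]
    groups: pd.Series
    differential: pd.DataFrame
    scores: pd.DataFrame
    comparison: Optional[association.MethodComparison]
    silencing_calls: pd.DataFrame
    consistency: Optional[silencing.ConsistencyReport]

    @property
    def candidate_genes(self) -> list[str]:
        return self.differential.index[
            self.differential["category"].isin(
                differential.SIGNIFICANT_CATEGORIES)
        ].tolist()

    def selected_genes(self, method: str = "regression-single") -> list[str]:
        sub = self.scores[(self.scores["method"] == method)
                          & self.scores["selected"]]
        return sub.sort_values("rank")["gene"].tolist()

    def report(self) -> pd.DataFrame:
        """Ranked per-gene report: category, per-method scores and
        selection flags, perc.diff."""
        genes = self.candidate_genes
        out = pd.DataFrame(index=pd.Index(genes, name="gene"))
        out["category"] = self.differential.loc[genes, "category"]
        out["delta_beta"] = self.differential.loc[genes, "delta_beta"]
        out["log2fc"] = self.differential.loc[genes, "log2fc"]
        for method in association.METHODS:
            sub = self.scores[self.scores["method"] == method].set_index("gene")
            out[f"score_{method}"] = sub["score"].reindex(genes)
            out[f"selected_{method}"] = (
                sub["selected"].reindex(genes).fillna(False).astype(bool)
            )
        out["perc_diff"] = self.silencing_calls["perc_diff"].reindex(genes)
        key = out["score_regression-single"].fillna(-np.inf)
        return out.loc[key.sort_values(ascending=False).index]

    def summary(self) -> str:
        n_h = int((self.groups == "CIMP-H").sum())
        n_l = int((self.groups == "Non-CIMP").sum())
        fr = self.filter_report
        cat_counts = self.differential["category"].value_counts()
        lines = [
            "Promoter methylation-expression analysis",
            "=" * 48,
            f"Samples: {n_h} CIMP-H vs {n_l} Non-CIMP"
            + (" (labels from sample sheet)" if self.cimp_records is None
               else " (classes from standardized CIMP-index)"),
            f"Probes: {fr.n_input} in, {fr.n_removed} removed "
            f"(sex={fr.n_sex_chrom}, snp={fr.n_snp_overlap}, "
            f"missing={fr.n_missing}), {fr.n_kept} kept",
            f"Promoters mapped: {len(self.promoter_map)} genes; "
            f"tested in both omics: {len(self.differential)}",
            "",
            "Differential categories:",
        ]
        for cat in differential.CATEGORIES:
            lines.append(f"  {cat:<16} {int(cat_counts.get(cat, 0)):>6}")
        lines += ["", "Association (candidates scored: "
                  f"{len(self.candidate_genes)}):"]
        for method in association.METHODS:
            sub = self.scores[self.scores["method"] == method]
            n_sel = int(sub["selected"].sum())
            med = sub["score"].median()
            lines.append(f"  {method:<20} median score {med:>8.4f}   "
                         f"selected {n_sel:>4}")
        if self.comparison is not None:
            for family in ("spearman", "regression"):
                h, p = self.comparison.kw[family]
                lines.append(f"  Kruskal-Wallis [{family}]: H={h:.4f}, p={p:.4g}")
        if self.consistency is not None:
            c = self.consistency
            lines += [
                "",
                f"Silencing consistency: overall perc.diff Q3={c.q3:.2f}; "
                f"identified genes at/above Q3: "
                + ("NA" if np.isnan(c.fraction_above_q3)
                   else f"{100 * c.fraction_above_q3:.1f}%"),
            ]
        return "\n".join(lines)
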