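"""Synthetic CIMP cohorts with planted ground truth.

The generator emulates the structure of a 450K + RNA-seq tumor cohort
stratified into CIMP-H and Non-CIMP groups: Beta-distributed probe betas
with promoter block structure (one CpG island per gene), global CIMP-H
hypermethylation, negative-binomial counts with variable library sizes,
and four gene roles —

* ``methylation-driven``: promoters hypermethylated in CIMP-H and
  log2 expression linear in promoter methylation (negative slope);
* ``dm-only``: hypermethylated, expression independent of methylation;
* ``de-only``: expression shifted between groups, methylation at baseline;
* ``null``: no planted effect.

Methylation of a hypermethylated promoter interpolates each probe between
its baseline level (Beta(2,10) mean) and its hypermethylated level
(Beta(10,2) mean) through a per-sample "dose" drawn Beta(12,2) in CIMP-H
and Beta(1,19) in Non-CIMP, so promoter methylation varies continuously
within groups and the planted linear methylation→expression relationship
is identifiable.  An optional multi-CpG mode gives every probe its own
dose and opposite-sign per-CpG expression coefficients, the regime in
which only the joint (single-CpG-predictors) regression can capture the
combined effect.

Decoy probes on X/Y, SNP-flagged and NA-bearing probes attached to decoy
gene symbols exercise the probe filters without touching the planted
promoters.  Identical (params, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import BetaMatrix, CountMatrix, ProbeAnnotation, SampleSheet

ROLES = ("methylation-driven", "dm-only", "de-only", "null")


class ParameterError(ValueError):
    """Infeasible generator settings."""


@dataclass
class CohortParams:
    n_genes: int = 200
    n_cimp_h: int = 40
    n_non_cimp: int = 40
    frac_methylation_driven: float = 0.10
    frac_dm_only: float = 0.10
    frac_de_only: float = 0.10
    #: log2-CPM units per unit promoter-mean beta for methylation-driven genes
    effect_slope: float = -3.0
    #: planted log2 fold change of de-only genes (CIMP-H minus Non-CIMP)
    de_only_log2fc: float = -2.0
    #: promoter sizes are 2 + Poisson(promoter_poisson_mean), truncated at 30
    promoter_poisson_mean: float = 4.0
    #: Beta(a,b) of baseline and hypermethylated per-probe mean levels
    baseline_beta: tuple[float, float] = (2.0, 10.0)
    hyper_beta: tuple[float, float] = (10.0, 2.0)
    #: Beta(a,b) of the per-sample hypermethylation dose, per group
    dose_cimp_h: tuple[float, float] = (25.0, 2.0)
    dose_non_cimp: tuple[float, float] = (1.0, 30.0)
    #: concentration of the per-cell Beta sampling noise around the mean level
    beta_concentration: float = 50.0
    #: additive CIMP-H shift of non-planted probe mean levels
    global_hyper_shift: float = 0.02
    #: log2 baseline abundance range (uniform); the floor keeps every gene
    #: quantifiable (>= ~32 baseline counts), emulating the low-expression
    #: filtering RNA-seq differential pipelines apply before testing
    log2_abundance_range: tuple[float, float] = (5.0, 10.0)
    nb_dispersion: float = 0.1
    #: library-size factors are exp(Uniform(log lo, log hi))
    libsize_factor_range: tuple[float, float] = (0.5, 2.0)
    frac_xy_probes: float = 0.05
    frac_snp_probes: float = 0.05
    frac_na_probes: float = 0.05
    #: per-probe doses and alternating-sign per-CpG expression coefficients
    multi_cpg_opposite_sign: bool = False

    def __post_init__(self) -> None:
        total = (self.frac_methylation_driven + self.frac_dm_only
                 + self.frac_de_only)
        if total > 1.0:
            raise ParameterError(f"role fractions sum to {total} > 1")
        if self.n_genes < 1 or self.n_cimp_h < 2 or self.n_non_cimp < 2:
            raise ParameterError("need >= 1 gene and >= 2 samples per group")


@dataclass
class Cohort:
    annot: ProbeAnnotation
    betas: BetaMatrix
    counts: CountMatrix
    samples: SampleSheet
    truth: pd.DataFrame  # index gene; role, effect_slope, planted_delta_beta, planted_log2fc
    params: CohortParams


def _clip_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.005, 0.995)


def _beta_noise(rng: np.random.Generator, mu: np.ndarray, nu: float) -> np.ndarray:
    mu = _clip_unit(mu)
    return rng.beta(mu * nu, (1.0 - mu) * nu)


def simulate_cohort(params: CohortParams | None = None, seed: int = 0) -> Cohort:
    """Generate one cohort; a pure function of (params, seed)."""
    params = params or CohortParams()
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_beta, rng_expr, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_h, n_l = params.n_cimp_h, params.n_non_cimp
    n_samples = n_h + n_l
    sample_ids = [f"T{i+1:03d}" for i in range(n_h)] + [
        f"N{i+1:03d}" for i in range(n_l)
    ]
    is_h = np.array([True] * n_h + [False] * n_l)

    genes = [f"G{i+1:04d}" for i in range(params.n_genes)]
    n_md = round(params.frac_methylation_driven * params.n_genes)
    n_dm = round(params.frac_dm_only * params.n_genes)
    n_de = round(params.frac_de_only * params.n_genes)
    roles = np.array(
        ["methylation-driven"] * n_md + ["dm-only"] * n_dm + ["de-only"] * n_de
        + ["null"] * (params.n_genes - n_md - n_dm - n_de)
    )
    roles = roles[rng_struct.permutation(params.n_genes)]

    sizes = 2 + np.minimum(
        rng_struct.poisson(params.promoter_poisson_mean, params.n_genes), 28
    )

    # --- manifest ------------------------------------------------------
    records = []
    probe_counter = 0

    def new_probe(chrom, gene, group, island, snp=False, prom_assoc=False):
        nonlocal probe_counter
        probe_counter += 1
        pid = f"cg{probe_counter:06d}"
        records.append(
            dict(probe_id=pid, chrom=chrom, pos=probe_counter * 1000,
                 genes=[gene] if gene else [], tss_groups=[group] if gene else [],
                 promoter_associated=prom_assoc, snp_overlap=snp,
                 island_id=island)
        )
        return pid

    probes_of: dict[str, list[str]] = {}
    for g, k in zip(genes, sizes):
        chrom = str(rng_struct.integers(1, 23))
        island = f"chr{chrom}:island_{g}"
        probes_of[g] = []
        for j in range(k):
            group = "TSS1500" if rng_struct.random() < 0.6 else "TSS200"
            probes_of[g].append(new_probe(chrom, g, group, island))

    n_core = probe_counter
    n_xy = round(params.frac_xy_probes * n_core)
    n_snp = round(params.frac_snp_probes * n_core)
    n_na = round(params.frac_na_probes * n_core)
    xy_ids = [
        new_probe("X" if rng_struct.random() < 0.5 else "Y",
                  f"XYDECOY{i+1:03d}", "TSS1500", "")
        for i in range(n_xy)
    ]
    snp_ids = [
        new_probe(str(rng_struct.integers(1, 23)), f"SNPDECOY{i+1:03d}",
                  "TSS1500", "", snp=True)
        for i in range(n_snp)
    ]
    na_ids = [
        new_probe(str(rng_struct.integers(1, 23)), f"NADECOY{i+1:03d}",
                  "TSS1500", "")
        for i in range(n_na)
    ]
    annot_frame = pd.DataFrame(records).set_index("probe_id")
    annot = ProbeAnnotation(annot_frame)
    probe_ids = annot_frame.index

    # --- methylation ---------------------------------------------------
    hyper_roles = {"methylation-driven", "dm-only"}
    mu_base = {p: rng_beta.beta(*params.baseline_beta) for p in probe_ids}
    mu = np.empty((len(probe_ids), n_samples))
    shift = np.where(is_h, params.global_hyper_shift, 0.0)
    row_of = {p: i for i, p in enumerate(probe_ids)}

    # non-planted probes: baseline + global CIMP-H shift
    for p in probe_ids:
        mu[row_of[p]] = _clip_unit(mu_base[p] + shift)

    truth_rows = []
    dose_a_h, dose_b_h = params.dose_cimp_h
    dose_a_l, dose_b_l = params.dose_non_cimp
    coef_of: dict[str, np.ndarray] = {}
    for g, role, k in zip(genes, roles, sizes):
        plist = probes_of[g]
        if role in hyper_roles:
            mu_hi = np.array([rng_beta.beta(*params.hyper_beta) for _ in plist])
            mu_lo = np.array([mu_base[p] for p in plist])
            if params.multi_cpg_opposite_sign:
                dose = np.where(
                    is_h,
                    rng_beta.beta(dose_a_h, dose_b_h, (k, n_samples)),
                    rng_beta.beta(dose_a_l, dose_b_l, (k, n_samples)),
                )
            else:
                d = np.where(
                    is_h,
                    rng_beta.beta(dose_a_h, dose_b_h, n_samples),
                    rng_beta.beta(dose_a_l, dose_b_l, n_samples),
                )
                dose = np.tile(d, (k, 1))
            block = mu_lo[:, None] + dose * (mu_hi - mu_lo)[:, None]
            for j, p in enumerate(plist):
                mu[row_of[p]] = _clip_unit(block[j])
        if role == "methylation-driven" and params.multi_cpg_opposite_sign:
            # mixed-sign per-CpG weights normalized to sum 1, so the net
            # promoter effect still equals effect_slope while individual
            # CpGs pull in opposite directions
            pattern = np.array([2.0 if j % 2 == 0 else -1.0 for j in range(k)])
            coef_of[g] = params.effect_slope * pattern / pattern.sum()
    betas_arr = _beta_noise(rng_beta, mu, params.beta_concentration)
    betas_df = pd.DataFrame(betas_arr, index=probe_ids, columns=sample_ids)
    for p in na_ids:
        s = rng_beta.integers(n_samples)
        betas_df.iloc[row_of[p], s] = np.nan
    betas = BetaMatrix(betas_df)

    # --- expression ----------------------------------------------------
    b0 = rng_expr.uniform(*params.log2_abundance_range, params.n_genes)
    log2_abund = np.empty((params.n_genes, n_samples))
    for i, (g, role) in enumerate(zip(genes, roles)):
        rows = [row_of[p] for p in probes_of[g]]
        mean_mu = mu[rows].mean(axis=0)
        base_mu = float(np.mean([mu_base[p] for p in probes_of[g]]))
        if role == "methylation-driven":
            if params.multi_cpg_opposite_sign:
                c = coef_of[g]
                centered = mu[rows] - np.array(
                    [mu_base[p] for p in probes_of[g]])[:, None]
                effect = c @ centered
                slope = float(c.sum())
            else:
                effect = params.effect_slope * (mean_mu - base_mu)
                slope = params.effect_slope
        elif role == "de-only":
            effect = np.where(is_h, params.de_only_log2fc, 0.0)
            slope = 0.0
        else:
            effect = np.zeros(n_samples)
            slope = 0.0
        log2_abund[i] = b0[i] + effect
        truth_rows.append(
            dict(
                gene=g,
                role=role,
                effect_slope=slope,
                planted_delta_beta=float(
                    mean_mu[is_h].mean() - mean_mu[~is_h].mean()),
                planted_log2fc=float(
                    log2_abund[i][is_h].mean() - log2_abund[i][~is_h].mean()),
            )
        )

    lib_lo, lib_hi = params.libsize_factor_range
    lib_factor = np.exp(rng_counts.uniform(np.log(lib_lo), np.log(lib_hi),
                                           n_samples))
    mu_counts = (2.0 ** log2_abund) * lib_factor
    inv_disp = 1.0 / params.nb_dispersion
    counts_arr = rng_counts.negative_binomial(
        inv_disp, inv_disp / (inv_disp + mu_counts)
    )
    counts = CountMatrix(
        pd.DataFrame(counts_arr.astype(np.int64), index=genes,
                     columns=sample_ids)
    )

    samples = SampleSheet(
        pd.DataFrame(
            {
                "cimp_status": np.where(is_h, "CIMP-H", "Non-CIMP"),
                "sample_type": "primary tumor",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return Cohort(annot=annot, betas=betas, counts=counts, samples=samples,
                  truth=truth, params=params)


def opposite_sign_params(**overrides) -> CohortParams:
    """Canonical settings for the multi-CpG opposite-sign scenario.

    The mechanism this mode exhibits — a joint regression on all promoter
    CpGs outperforming summary predictors — requires per-CpG methylation
    heterogeneity *within* groups, so the dose distributions are wider
    (Beta(6,1) / Beta(1,6)) than in the standard scenario; the net slope
    is −4 so the planted genes' net fold change still clears the
    |log2FC| ≥ 1.3 differential gate at the wider dose separation.
    """
    settings = dict(
        multi_cpg_opposite_sign=True,
        effect_slope=-4.0,
        dose_cimp_h=(6.0, 1.0),
        dose_non_cimp=(1.0, 6.0),
    )
    settings.update(overrides)
    return CohortParams(**settings)


# ---------------------------------------------------------------------------
# worked example
# ---------------------------------------------------------------------------

_FIXTURE_SEED = 20240117


def worked_example_fixture() -> Cohort:
    """Tiny deterministic cohort with hand-checkable values.

    12 genes, 10 CIMP-H + 10 Non-CIMP samples.  Landmarks:

    * ``F01`` has 3 promoter probes whose betas in sample ``T001`` are
      exactly [0.1, 0.35, 0.6] (ratio metric at β ≥ 0.3 → 2/3);
    * ``F02`` is methylation-driven with log2 expression
      10 − 3·(promoter-mean beta) + N(0, 0.1) — hyper-down, and selected
      by the regression-average scorer;
    * ``F03`` is hypermethylated and upregulated (slope +3);
    * ``F04`` is dm-only, ``F05`` de-only (log2FC −2), ``F06``–``F11``
      null, ``F12`` a constant high-expression filler that pins every
      library size at exactly 1e6;
    * one X-chromosome probe (gene ``FX``) that the probe filter removes.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    n_h = n_l = 10
    sample_ids = [f"T{i+1:03d}" for i in range(n_h)] + [
        f"N{i+1:03d}" for i in range(n_l)
    ]
    is_h = np.array([True] * n_h + [False] * n_l)
    records = []
    beta_rows: dict[str, np.ndarray] = {}

    def add_probe(pid, chrom, gene, group, island, betas):
        records.append(dict(probe_id=pid, chrom=chrom, pos=len(records) * 500 + 1,
                            genes=[gene], tss_groups=[group],
                            promoter_associated=False, snp_overlap=False,
                            island_id=island))
        beta_rows[pid] = np.asarray(betas, dtype=float)

    def noisy(level, spread=0.03):
        return np.clip(level + rng.uniform(-spread, spread, 20), 0.01, 0.99)

    # F01: flat gene carrying the ratio-metric example in T001
    for j, level in enumerate([0.1, 0.35, 0.6]):
        vals = noisy(level)
        vals[0] = level  # T001 exactly at the landmark value
        add_probe(f"cg_F01_{j+1}", "1", "F01", "TSS1500", "chr1:isl_F01", vals)

    def hyper_gene(gene, chrom, n_probes=2):
        """Promoter-mean beta ~0.7 in CIMP-H, ~0.2 in Non-CIMP."""
        mean_beta = np.where(is_h, rng.uniform(0.6, 0.8, 20),
                             rng.uniform(0.12, 0.28, 20))
        for j in range(n_probes):
            offs = (j - (n_probes - 1) / 2) * 0.04
            add_probe(f"cg_{gene}_{j+1}", chrom, gene, "TSS200",
                      f"chr{chrom}:isl_{gene}", np.clip(mean_beta + offs, 0.01, 0.99))
        return mean_beta

    def flat_gene(gene, chrom, level=0.2, n_probes=2):
        for j in range(n_probes):
            add_probe(f"cg_{gene}_{j+1}", chrom, gene, "TSS1500",
                      f"chr{chrom}:isl_{gene}", noisy(level))

    mean_f02 = hyper_gene("F02", "2")
    mean_f03 = hyper_gene("F03", "3")
    mean_f04 = hyper_gene("F04", "4")   # dm-only
    flat_gene("F05", "5")            # de-only
    for i in range(6, 12):
        flat_gene(f"F{i:02d}", str(i))
    flat_gene("F12", "12", n_probes=1)
    add_probe("cg_FX_1", "X", "FX", "TSS1500", "", noisy(0.5))

    annot = ProbeAnnotation(pd.DataFrame(records).set_index("probe_id"))
    betas = BetaMatrix(pd.DataFrame(beta_rows, index=sample_ids).T
                       .loc[list(beta_rows)])

    # expression on the log2-CPM scale (library sizes pinned to 1e6 below)
    y = {}
    promoter_mean = {"F02": (beta_rows["cg_F02_1"] + beta_rows["cg_F02_2"]) / 2,
                     "F03": (beta_rows["cg_F03_1"] + beta_rows["cg_F03_2"]) / 2}
    y["F01"] = 8.0 + rng.normal(0, 0.1, 20)
    y["F02"] = 10.0 - 3.0 * promoter_mean["F02"] + rng.normal(0, 0.1, 20)
    y["F03"] = 5.0 + 3.0 * promoter_mean["F03"] + rng.normal(0, 0.1, 20)
    y["F04"] = 7.0 + rng.normal(0, 0.1, 20)
    y["F05"] = 9.0 + np.where(is_h, -2.0, 0.0) + rng.normal(0, 0.1, 20)
    for i in range(6, 12):
        y[f"F{i:02d}"] = rng.uniform(5, 9) + rng.normal(0, 0.1, 20)

    lib = 1_000_000
    count_rows = {
        g: np.maximum(np.rint(2.0 ** vals * (lib + 1) / 1e6 - 0.5), 0
                      ).astype(np.int64)
        for g, vals in y.items()
    }
    partial = np.sum(list(count_rows.values()), axis=0)
    count_rows["F12"] = (lib - partial).astype(np.int64)
    genes = [f"F{i:02d}" for i in range(1, 13)]
    counts = CountMatrix(pd.DataFrame(count_rows, index=sample_ids).T.loc[genes])

    samples = SampleSheet(
        pd.DataFrame(
            {"cimp_status": np.where(is_h, "CIMP-H", "Non-CIMP"),
             "sample_type": "primary tumor"},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = pd.DataFrame(
        {
            "role": ["null", "methylation-driven", "methylation-driven",
                     "dm-only", "de-only"] + ["null"] * 7,
            "effect_slope": [0.0, -3.0, 3.0, 0.0, 0.0] + [0.0] * 7,
            "planted_delta_beta": [
                0.0,
                float(mean_f02[is_h].mean() - mean_f02[~is_h].mean()),
                float(mean_f03[is_h].mean() - mean_f03[~is_h].mean()),
                float(mean_f04[is_h].mean() - mean_f04[~is_h].mean()),
                0.0, *[0.0] * 7,
            ],
            "planted_log2fc": [
                0.0,
                float(-3.0 * (mean_f02[is_h].mean() - mean_f02[~is_h].mean())),
                float(3.0 * (mean_f03[is_h].mean() - mean_f03[~is_h].mean())),
                0.0, -2.0, *[0.0] * 7,
            ],
        },
        index=pd.Index(genes, name="gene"),
    )
    return Cohort(annot=annot, betas=betas, counts=counts, samples=samples,
                  truth=truth, params=CohortParams(n_genes=12, n_cimp_h=10,
                                                   n_non_cimp=10))
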