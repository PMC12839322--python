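import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from promethex.association import (
    METHODS,
    REGRESSION_METHODS,
    SPEARMAN_METHODS,
    compare_methods,
    fisher_combine,
    fit_promoter_regression,
    score_regression,
    score_spearman,
    select_genes,
    spearman_rho,
)
from promethex.config import Config

from .oracles import ols_brute, spearman_brute


class TestSpearmanRho:
    def test_hand_computed_rank_correlation(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_perfect_correlations(self):
        x = np.arange(5.0)
        assert spearman_rho(x, x) == (1.0, 0.0)
        assert spearman_rho(x, -x) == (-1.0, 0.0)

    def test_zero_variance_returns_nan(self):
        rho, p = spearman_rho([1.0] * 6, np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_short_or_mismatched_inputs(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [3, 2, 1])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3, 4, 5], [1, 2, 3, 4])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = rng.integers(5, 30)
            x = np.round(rng.normal(size=n), 1)  # rounding makes ties
            y = np.round(rng.normal(size=n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman_rho(x, y)
            rho_b, p_b = spearman_brute(x, y)
            assert rho == pytest.approx(rho_b, abs=1e-12)
            assert p == pytest.approx(p_b, abs=1e-12)

    @given(st.lists(st.integers(-10**6, 10**6), min_size=6, max_size=20,
                    unique=True))
    def test_invariant_under_monotone_transforms(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        x = np.asarray(xs, dtype=float) / 1000.0  # well-spaced reals
        y = rng.normal(size=len(xs))
        base, _ = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 100), y)[0] == pytest.approx(base, abs=1e-9)
        assert spearman_rho(x ** 3, y)[0] == pytest.approx(base, abs=1e-9)
        assert spearman_rho(x, 2 * y + 5)[0] == pytest.approx(base, abs=1e-9)


class TestFisherCombine:
    def test_matches_chi2_formula(self):
        from scipy import stats
        ps = [0.01, 0.2, 0.5]
        expected = stats.chi2.sf(-2 * np.log(ps).sum(), 6)
        assert fisher_combine(ps) == pytest.approx(expected, rel=1e-12)

    def test_zero_p_is_floored_not_fatal(self):
        combined = fisher_combine([0.0, 0.5])
        assert np.isfinite(combined) and combined < 1e-290


class TestPromoterRegression:
    def test_perfect_linear_fit(self):
        x = np.linspace(0, 1, 10)
        fit = fit_promoter_regression(x[:, None], 3 - 2 * x)
        assert fit.adj_r2 == 1.0 and fit.model_p == 0.0
        assert fit.status == "ok" and fit.k_eff == 1

    def test_known_r2_gives_textbook_adjustment(self):
        # constructed so R^2 is exactly 0.8 at n=5, k=1:
        # residuals orthogonal to [1, x] with SSE = SSR/4
        x = np.arange(5.0)
        e = np.array([2.0, -1.0, -2.0, -1.0, 2.0]) * np.sqrt(2.5 / 14)
        fit = fit_promoter_regression(x[:, None], x + e)
        assert fit.adj_r2 == pytest.approx(1 - 0.2 * 4 / 3, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            k = int(rng.integers(1, min(6, n - 4)))
            X = rng.normal(size=(n, k))
            y = X @ rng.normal(size=k) + rng.normal(size=n)
            fit = fit_promoter_regression(X, y)
            _, adj_b, p_b = ols_brute(X, y)
            assert fit.adj_r2 == pytest.approx(adj_b, abs=1e-9)
            assert fit.model_p == pytest.approx(p_b, abs=1e-9)

    def test_pure_noise_has_near_zero_mean_adjusted_r2(self):
        rng = np.random.default_rng(43)
        vals = []
        for _ in range(200):
            X = rng.normal(size=(60, 2))
            y = rng.normal(size=60)
            vals.append(fit_promoter_regression(X, y).adj_r2)
        assert abs(np.mean(vals)) < 0.05

    def test_duplicated_predictor_is_rank_reduced(self):
        rng = np.random.default_rng(47)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        dup = np.column_stack([x, x, 3 * x - 1])
        fit = fit_promoter_regression(dup, y)
        single = fit_promoter_regression(x[:, None], y)
        assert fit.k_eff == 1
        assert fit.adj_r2 == pytest.approx(single.adj_r2, abs=1e-10)

    def test_underdetermined_and_zero_variance_handling(self):
        rng = np.random.default_rng(53)
        X = rng.normal(size=(6, 5))
        fit = fit_promoter_regression(X, rng.normal(size=6))
        assert fit.status == "underdetermined" and np.isnan(fit.adj_r2)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_promoter_regression(X[:, :1], np.ones(6))

    def test_constant_predictors_explain_nothing(self):
        y = np.random.default_rng(59).normal(size=12)
        fit = fit_promoter_regression(np.ones((12, 2)), y)
        assert fit.adj_r2 == 0.0 and fit.model_p == 1.0 and fit.k_eff == 0

    def test_joint_fit_never_explains_less_than_the_average(self):
        # R^2 (unadjusted) of all CpGs >= R^2 of their mean, since the mean
        # is a linear combination of the predictors
        rng = np.random.default_rng(61)
        for _ in range(20):
            X = rng.uniform(0.0, 1.0, size=(30, 4))
            y = X @ rng.normal(size=4) + rng.normal(scale=0.5, size=30)
            single = fit_promoter_regression(X, y)
            avg = fit_promoter_regression(X.mean(axis=1, keepdims=True), y)
            n = 30
            r2_single = 1 - (1 - single.adj_r2) * (n - single.k_eff - 1) / (n - 1)
            r2_avg = 1 - (1 - avg.adj_r2) * (n - avg.k_eff - 1) / (n - 1)
            assert r2_single >= r2_avg - 1e-10


def gene_inputs(n=30, k=3, seed=67, slope=-3.0, noise=0.3):
    rng = np.random.default_rng(seed)
    betas = pd.DataFrame(rng.uniform(0.05, 0.95, (k, n)),
                         index=[f"p{i}" for i in range(k)],
                         columns=[f"s{j}" for j in range(n)])
    mean_beta = betas.mean(axis=0)
    expr = pd.Series(8 + slope * mean_beta + rng.normal(0, noise, n),
                     index=betas.columns)
    summaries = {"average": mean_beta,
                 "ratio": (betas >= 0.3).mean(axis=0)}
    return betas, summaries, expr


class TestGeneScorers:
    def test_single_cpg_promoter_collapses_single_and_average(self):
        betas, summaries, expr = gene_inputs(k=1)
        s_single = score_spearman(betas, summaries, expr, "single")
        s_avg = score_spearman(betas, summaries, expr, "average")
        assert s_single["score"] == pytest.approx(s_avg["score"], abs=1e-12)
        r_single = score_regression(betas, summaries, expr, "single")
        r_avg = score_regression(betas, summaries, expr, "average")
        assert r_single["score"] == pytest.approx(r_avg["score"], abs=1e-12)

    def test_spearman_single_is_mean_of_per_cpg_rhos(self):
        betas, summaries, expr = gene_inputs(k=3)
        rec = score_spearman(betas, summaries, expr, "single")
        per_cpg = [spearman_rho(betas.loc[p], expr)[0] for p in betas.index]
        assert rec["score"] == pytest.approx(np.mean(per_cpg), abs=1e-12)
        assert rec["n_cpgs"] == 3 and rec["status"] == "ok"

    def test_degenerate_ratio_summary_gives_na_score(self):
        betas, summaries, expr = gene_inputs(k=2)
        summaries["ratio"] = pd.Series(1.0, index=expr.index)  # constant
        rec = score_spearman(betas, summaries, expr, "ratio")
        assert np.isnan(rec["score"]) and rec["status"] == "degenerate"

    def test_opposite_sign_cpgs_favor_the_joint_regression(self):
        rng = np.random.default_rng(71)
        n = 60
        b1, b2 = rng.uniform(0.1, 0.9, n), rng.uniform(0.1, 0.9, n)
        betas = pd.DataFrame([b1, b2], index=["p1", "p2"],
                             columns=[f"s{j}" for j in range(n)])
        expr = pd.Series(7 - 4 * b1 + 4 * b2 + rng.normal(0, 0.2, n),
                         index=betas.columns)
        summaries = {"average": betas.mean(axis=0),
                     "ratio": (betas >= 0.3).mean(axis=0)}
        single = score_regression(betas, summaries, expr, "single")
        avg = score_regression(betas, summaries, expr, "average")
        assert single["score"] > 0.9 > avg["score"]


class TestSelection:
    def frame(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "method", "score", "p",
                                         "adj_p"])
        df["n_cpgs"] = 1
        df["n_samples"] = 50
        df["status"] = "ok"
        return df

    def test_selection_rules_and_ranking(self):
        scores = self.frame([
            ("MLH1", "regression-single", 0.916, 1e-50, 1e-48),
            ("GENE2", "regression-single", 0.62, 1e-9, 1e-8),
            ("GENE3", "regression-single", 0.60, 0.2, 0.3),     # p too high
            ("GENE4", "spearman-average", 0.40, 1e-9, 1e-8),    # not strict >
            ("GENE5", "spearman-average", -0.85, 1e-12, 1e-10),  # |rho| used
        ])
        out = select_genes(scores, Config())
        sel = out.set_index("gene")
        assert sel.loc["MLH1", "selected"] and sel.loc["MLH1", "rank"] == 1
        assert sel.loc["GENE2", "selected"] and sel.loc["GENE2", "rank"] == 2
        assert not sel.loc["GENE3", "selected"]
        assert not sel.loc["GENE4", "selected"]
        assert sel.loc["GENE5", "selected"] and sel.loc["GENE5", "rank"] == 1

    def test_ties_rank_lexicographically(self):
        scores = self.frame([
            ("B", "regression-single", 0.7, 1e-9, 1e-8),
            ("A", "regression-single", 0.7, 1e-9, 1e-8),
        ])
        out = select_genes(scores, Config()).set_index("gene")
        assert out.loc["A", "rank"] == 1 and out.loc["B", "rank"] == 2

    def test_lowering_threshold_only_adds_genes(self):
        rng = np.random.default_rng(73)
        rows = [(f"G{i}", "regression-single", rng.uniform(0, 1),
                 1e-6, 1e-5) for i in range(40)]
        scores = self.frame(rows)
        strict = select_genes(scores, Config(adj_r2_min=0.6))
        loose = select_genes(scores, Config(adj_r2_min=0.3))
        strict_set = set(strict.loc[strict["selected"], "gene"])
        loose_set = set(loose.loc[loose["selected"], "gene"])
        assert strict_set <= loose_set


class TestCompareMethods:
    def full_frame(self, per_gene_scores):
        """per_gene_scores: gene -> {method: score}"""
        rows = []
        for gene, by_method in per_gene_scores.items():
            for method in METHODS:
                rows.append({"gene": gene, "method": method,
                             "score": by_method.get(method, 0.1),
                             "p": 0.01, "adj_p": 0.02, "n_cpgs": 1,
                             "n_samples": 50, "status": "ok",
                             "selected": False, "rank": pd.NA})
        return pd.DataFrame(rows)

    def test_identical_distributions_give_h0_p1(self):
        scores = self.full_frame({f"G{i}": {} for i in range(5)})
        comp = compare_methods(scores)
        assert comp.kw["spearman"] == (0.0, 1.0)
        assert comp.kw["regression"] == (0.0, 1.0)

    def test_argmax_credit_single_winner_and_ties(self):
        scores = self.full_frame({
            "G1": {"regression-single": 0.6, "regression-average": 0.3,
                   "regression-ratio": 0.3},
            "G2": {"regression-single": 0.5, "regression-average": 0.5,
                   "regression-ratio": 0.2},
        })
        comp = compare_methods(scores)
        assert comp.argmax_counts["regression-single"] == 2
        assert comp.argmax_counts["regression-average"] == 1
        assert comp.argmax_counts["regression-ratio"] == 0
        # with ties credited, total credits cover every scored gene
        reg_total = sum(comp.argmax_counts[m] for m in REGRESSION_METHODS)
        assert reg_total >= 2

    def test_spearman_family_compared_on_absolute_rho(self):
        scores = self.full_frame({
            "G1": {"spearman-single": -0.9, "spearman-average": 0.5,
                   "spearman-ratio": 0.5},
        })
        comp = compare_methods(scores)
        assert comp.argmax_counts["spearman-single"] == 1

    def test_overlap_matrix_reflects_selection(self):
        scores = self.full_frame({"G1": {}, "G2": {}})
        scores.loc[(scores.gene == "G1")
                   & (scores.method == "regression-single"), "selected"] = True
        comp = compare_methods(scores)
        assert bool(comp.overlap.loc["G1", "regression-single"])
        assert not bool(comp.overlap.loc["G2", "regression-single"])
        assert set(comp.overlap.columns) == set(METHODS)
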