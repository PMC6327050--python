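"""Driver correlation, gene-set overlap enrichment and outlier Z-scores."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regfine.programs import (correlated_gene_set, overlap_binomial,
                              spearman_correlate, top_de_genes,
                              translocation_zscore)
from regfine.simulate import (SimulationConfig, simulate_expression_cohort,
                              simulate_translocated_cases)


def expr_matrix(rows: dict, samples=None):
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    return df


class TestSpearman:
    def test_monotone_square_is_one(self):
        x = np.arange(1.0, 8.0)
        em = expr_matrix({"DRIVER": x, "g": x**2})
        out = spearman_correlate(em, "DRIVER")
        assert out.loc["g", "rho"] == pytest.approx(1.0)
        assert out.loc["g", "exact_monotone"]
        assert out.loc["g", "p"] == 0.0

    def test_hand_example_minus_half(self):
        em = expr_matrix({"DRIVER": [1, 2, 3, 4], "g": [3, 1, 2, 4]})
        out = spearman_correlate(em, "DRIVER")
        ref = stats.spearmanr([1, 2, 3, 4], [3, 1, 2, 4]).statistic
        assert out.loc["g", "rho"] == pytest.approx(ref, abs=1e-12)

    def test_printed_triple(self):
        # rho([1,2,3],[3,1,2]) = -0.5; padded to meet the n >= 4 requirement
        # by computing directly on ranks
        rho = np.corrcoef(stats.rankdata([1, 2, 3]), stats.rankdata([3, 1, 2]))[0, 1]
        assert rho == pytest.approx(-0.5, abs=1e-12)

    def test_driver_vs_itself(self, rng):
        em = expr_matrix({"DRIVER": rng.normal(size=10), "g": rng.normal(size=10)})
        out = spearman_correlate(em, "DRIVER")
        assert out.loc["DRIVER", "rho"] == pytest.approx(1.0)

    def test_constant_gene_flagged_nan(self, rng):
        em = expr_matrix({"DRIVER": rng.normal(size=8), "flat": np.ones(8)})
        assert math.isnan(spearman_correlate(em, "DRIVER").loc["flat", "rho"])

    def test_matches_scipy_on_random_matrix(self, rng):
        em = pd.DataFrame(rng.normal(size=(20, 15)),
                          index=[f"g{i}" for i in range(20)])
        em.index = ["DRIVER"] + list(em.index[1:])
        out = spearman_correlate(em, "DRIVER")
        for gene in em.index[1:6]:
            rho, p = stats.spearmanr(em.loc["DRIVER"], em.loc[gene])
            assert out.loc[gene, "rho"] == pytest.approx(rho, abs=1e-12)
            assert out.loc[gene, "p"] == pytest.approx(p, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        em = pd.DataFrame(rng.normal(size=(5, 12)),
                          index=["DRIVER", "a", "b", "c", "d"])
        base = spearman_correlate(em, "DRIVER")["rho"]
        em2 = em.copy()
        em2.loc["a"] = np.exp(em2.loc["a"])
        assert spearman_correlate(em2, "DRIVER").loc["a", "rho"] == pytest.approx(
            base.loc["a"], abs=1e-12)


class TestCorrelatedGeneSet:
    def test_threshold_one_takes_all_but_driver(self, rng):
        em = pd.DataFrame(rng.normal(size=(6, 10)),
                          index=["DRIVER", "a", "b", "c", "d", "e"])
        out = spearman_correlate(em, "DRIVER")
        assert correlated_gene_set(out, "DRIVER", 1.01) == {"a", "b", "c", "d", "e"}

    def test_planted_targets_recovered(self):
        """rho=0.9 targets at n=117 all pass the P < 5e-4 cut over 20 seeds."""
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_genes=300, n_correlated=20,
                                   target_rho=0.9, de_size=20, de_overlap=5)
            expr, truth = simulate_expression_cohort(cfg)
            out = spearman_correlate(expr, "DRIVER")
            got = correlated_gene_set(out, "DRIVER", 5e-4)
            assert set(truth["correlated_genes"]) <= got

    def test_fdr_adjust_option_is_stricter(self, rng):
        em = pd.DataFrame(rng.normal(size=(50, 20)),
                          index=["DRIVER"] + [f"g{i}" for i in range(49)])
        out = spearman_correlate(em, "DRIVER")
        raw = correlated_gene_set(out, "DRIVER", 0.1)
        adj = correlated_gene_set(out, "DRIVER", 0.1, adjust="fdr_bh")
        assert adj <= raw


class TestOverlapBinomial:
    def test_a_equals_universe_p_one(self):
        uni = {f"g{i}" for i in range(20)}
        b = {f"g{i}" for i in range(5)}
        res = overlap_binomial(uni, uni, b)
        assert res.overlap == 5 and res.p == pytest.approx(1.0)

    def test_exact_tail_example(self):
        uni = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = overlap_binomial(uni, a, b)
        exact = sum(Fraction(math.comb(10, k)) * Fraction(1, 10)**k
                    * Fraction(9, 10)**(10 - k) for k in range(5, 11))
        assert res.overlap == 5
        assert res.p == pytest.approx(float(exact), rel=1e-10)
        assert float(exact) == pytest.approx(1.64e-3, rel=0.01)

    def test_zero_overlap_p_one(self):
        uni = {"a", "b", "c", "d"}
        assert overlap_binomial(uni, {"a"}, {"b"}).p == pytest.approx(1.0)

    def test_subset_violation_lists_offenders(self):
        with pytest.raises(ValueError, match="zzz"):
            overlap_binomial({"a", "b"}, {"a", "zzz"}, {"b"})

    def test_hypergeometric_option(self):
        uni = {f"g{i}" for i in range(30)}
        a = {f"g{i}" for i in range(6)}
        b = {f"g{i}" for i in range(3)} | {"g10", "g11"}
        res = overlap_binomial(uni, a, b, method="hypergeometric")
        assert res.p == pytest.approx(float(stats.hypergeom.sf(2, 30, 6, 5)))

    def test_agrees_with_monte_carlo_resampling(self):
        """Binomial tail within 3 MC SDs of random-subset resampling (N<=200)."""
        r = np.random.default_rng(12)
        uni = [f"g{i}" for i in range(150)]
        a = set(uni[:30])
        b = set(r.choice(uni, size=25, replace=False))
        res = overlap_binomial(set(uni), a, b)
        draws = 10_000
        hits = sum(len(a & set(r.choice(uni, size=25, replace=False))) >= res.overlap
                   for _ in range(draws))
        mc = hits / draws
        sd = math.sqrt(max(mc * (1 - mc), 1e-9) / draws)
        # binomial (with replacement) vs subset draw differ slightly; allow both
        assert abs(res.p - mc) < 3 * sd + 0.02


class TestTopDeGenes:
    def _table(self):
        return pd.DataFrame({"gene": ["a", "b", "c", "d"],
                             "padj": [0.01, 0.001, 0.01, 0.5],
                             "log_fc": [1.0, 0.1, -3.0, 2.0]})

    def test_k_equals_table_size(self):
        assert top_de_genes(self._table(), k=4) == ["b", "c", "a", "d"]

    def test_tie_break_by_abs_lfc(self):
        top = top_de_genes(self._table(), k=2)
        assert top == ["b", "c"]  # c beats a on |logFC| at tied padj

    def test_k_too_large_warns(self):
        with pytest.warns(UserWarning):
            assert len(top_de_genes(self._table(), k=10)) == 4

    def test_planted_de_truth_recovered(self):
        cfg = SimulationConfig(seed=6, n_genes=400, n_correlated=30,
                               de_size=150, de_overlap=20)
        _, truth = simulate_expression_cohort(cfg)
        rng = np.random.default_rng(1)
        de_genes = truth["de_genes"]
        others = [f"G{i:05d}" for i in range(399)]
        others = [g for g in others if g not in set(de_genes)]
        table = pd.DataFrame({
            "gene": de_genes + others,
            "padj": np.r_[rng.uniform(0, 1e-6, len(de_genes)),
                          rng.uniform(0.2, 1, len(others))],
            "log_fc": rng.normal(0, 1, len(de_genes) + len(others))})
        assert set(top_de_genes(table, k=150)) == set(de_genes)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            top_de_genes(pd.DataFrame({"gene": ["a"]}), k=1)


class TestTranslocationZscore:
    def test_case_at_mean_is_zero(self):
        em = expr_matrix({"g": [1.0, 2.0, 3.0, 2.0]})
        flags = pd.Series([False, False, False, True], index=em.columns)
        res = translocation_zscore(em, flags, "g")
        assert list(res.case_z.values())[0] == pytest.approx(0.0)

    def test_hand_computation(self):
        em = expr_matrix({"g": [1.0, 2.0, 3.0, 4.0]})
        flags = pd.Series([False, False, False, True], index=em.columns)
        res = translocation_zscore(em, flags, "g")
        assert res.mean_z == pytest.approx(2.0)  # mean 2, sample SD 1

    def test_zero_sd_flagged(self):
        em = expr_matrix({"g": [5.0, 5.0, 5.0, 9.0]})
        flags = pd.Series([False, False, False, True], index=em.columns)
        assert translocation_zscore(em, flags, "g").undefined

    def test_planted_z_recovery(self):
        """Planted Z = 4.6 recovered within 15% over 20 seeds."""
        zs = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_genes=50, n_correlated=5,
                                   de_size=5, de_overlap=2, target_z=4.6)
            cohort, _ = simulate_expression_cohort(cfg)
            full, flags, _ = simulate_translocated_cases(cohort, cfg)
            zs.append(translocation_zscore(full, flags, "DRIVER").mean_z)
        assert np.mean(zs) == pytest.approx(4.6, rel=0.15)

    def test_null_case_standardised(self):
        """A case drawn from the cohort model has z with mean ~0 and SD ~1."""
        r = np.random.default_rng(3)
        zs = []
        for _ in range(1000):
            cohort = r.normal(10, 2, 60)
            case = r.normal(10, 2)
            zs.append((case - cohort.mean()) / cohort.std(ddof=1))
        assert abs(np.mean(zs)) < 0.1
        assert 0.9 < np.std(zs) < 1.15

    def test_flags_only_on_appended_cases(self):
        cfg = SimulationConfig(seed=2, n_genes=30, n_correlated=3,
                               de_size=3, de_overlap=1)
        cohort, _ = simulate_expression_cohort(cfg)
        full, flags, truth = simulate_translocated_cases(cohort, cfg)
        assert set(flags[flags].index) == set(truth["translocated_cases"])
        assert not flags[cohort.columns].any()
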