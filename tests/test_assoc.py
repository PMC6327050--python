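"""Association, meta-analysis, INFO scoring, LD capture and conditional tests."""

import math

import numpy as np
import pytest
from scipy import stats

from regfine.assoc import (
    allelic_association, conditional_association, fixed_effect_meta,
    info_filter, info_score, ld_block_capture, ld_r2,
)
from regfine.simulate import SimulationConfig, simulate_case_control, simulate_ld_proxies


def _dosages(n2, n1, n0):
    return np.array([2] * n2 + [1] * n1 + [0] * n0)


class TestAllelicAssociation:
    def test_cross_product_odds_ratio(self):
        # case alleles 60 risk / 40 other, controls 40 / 60
        res = allelic_association(_dosages(30, 0, 20), _dosages(20, 0, 30))
        assert res.odds_ratio == pytest.approx((60 * 60) / (40 * 40))
        assert res.odds_ratio == pytest.approx(math.exp(res.beta))

    def test_null_equal_frequencies(self):
        res = allelic_association(_dosages(0, 10, 0), _dosages(0, 10, 0))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        # all cases homozygous risk -> zero non-risk cell; correction keeps OR finite
        res = allelic_association(_dosages(10, 0, 0), _dosages(5, 0, 5))
        a, b, c, d = 20.5, 0.5, 10.5, 10.5
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))
        assert math.isfinite(res.se)

    def test_monomorphic_flagged_not_raised(self):
        res = allelic_association(_dosages(0, 0, 5), _dosages(0, 0, 5))
        assert res.undefined and math.isnan(res.odds_ratio)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            allelic_association(np.array([]), _dosages(1, 1, 1))

    def test_or_recovery_from_simulation(self):
        """Mean estimated OR within 10% of the simulated OR 1.45 (20 seeds)."""
        ests = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_cases=5000, n_controls=5000,
                                   maf=0.3, odds_ratio=1.45)
            geno, pheno, _ = simulate_case_control(cfg)
            res = allelic_association(geno.loc[pheno == 1, "rs_lead"],
                                      geno.loc[pheno == 0, "rs_lead"])
            ests.append(res.odds_ratio)
        assert np.mean(ests) == pytest.approx(1.45, rel=0.10)


class TestFixedEffectMeta:
    def test_single_study_identity(self):
        m = fixed_effect_meta([(0.37, 0.05)])
        assert (m.beta, m.se) == (0.37, 0.05)
        assert m.Q == 0.0 and m.p_het == 1.0

    def test_hand_formula_example(self):
        m = fixed_effect_meta([(0.5, 0.1), (0.3, 0.2)])
        assert m.beta == pytest.approx(0.46, abs=1e-9)
        assert m.se == pytest.approx(1 / math.sqrt(125), abs=1e-9)
        assert m.Q == pytest.approx(0.8, abs=1e-9)
        assert m.p_het == pytest.approx(stats.chi2.sf(0.8, 1), abs=1e-9)

    def test_identical_studies_homogeneous(self):
        m = fixed_effect_meta([(0.2, 0.1)] * 3)
        assert m.Q == pytest.approx(0.0, abs=1e-12)
        assert m.p_het == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_k_copies_scale_se(self, k):
        base = (0.31, 0.07)
        m = fixed_effect_meta([base] * k)
        assert m.beta == pytest.approx(base[0])
        assert m.se == pytest.approx(base[1] / math.sqrt(k))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fixed_effect_meta([])


class TestInfoScore:
    def test_point_masses_give_one(self):
        r = info_score(np.array([[1, 0, 0], [0, 0, 1.0]]))
        assert r.info == pytest.approx(1.0)

    def test_two_sample_hand_formula(self):
        r = info_score(np.array([[0.5, 0.5, 0], [0, 1, 0.0]]))
        assert r.theta_hat == pytest.approx(0.375)
        assert r.info == pytest.approx(1 - 0.25 / 0.9375, abs=1e-9)

    def test_monomorphic_convention(self):
        assert info_score(np.array([[1.0, 0, 0]] * 4)).info == 1.0

    def test_bad_triple_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            info_score(np.array([[0.5, 0.4, 0.0]]))

    def test_filter_threshold_semantics(self):
        res = {"a": info_score(np.array([[1, 0, 0], [0, 0, 1.0]]), "a"),
               "b": info_score(np.array([[0.5, 0.5, 0], [0, 1, 0.0]]), "b")}
        assert info_filter(res, 0.8) == ["a"]

    def test_matches_independent_formula_on_random_tables(self, rng):
        """Ratio formula re-implemented with plain loops, 1000 random tables."""
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            raw = rng.random((n, 3))
            post = raw / raw.sum(axis=1, keepdims=True)
            e = [p1 + 2 * p2 for _, p1, p2 in post]
            f = [p1 + 4 * p2 for _, p1, p2 in post]
            theta = sum(e) / (2 * n)
            expect = 1.0 if theta in (0, 1) else 1 - sum(
                fi - ei**2 for fi, ei in zip(f, e)) / (2 * n * theta * (1 - theta))
            expect = min(max(expect, 0.0), 1.0)
            worst = max(worst, abs(info_score(post).info - expect))
        assert worst < 1e-10


class TestLdR2:
    def test_identical_and_complementary(self, rng):
        a = rng.binomial(2, 0.3, 50).astype(float)
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(ld_r2(np.zeros(10), np.arange(10)))

    def test_independent_variants_near_zero(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            r2 = ld_r2(r.binomial(2, 0.3, 1000), r.binomial(2, 0.3, 1000))
            hits += r2 < 0.02
        assert hits >= 95


class TestLdBlockCapture:
    @staticmethod
    def brute_force(lead, dosages, r2_min, maf_min):
        captured = []
        for var in dosages.columns:
            dos = dosages[var].to_numpy(dtype=float)
            maf = min(dos.mean() / 2, 1 - dos.mean() / 2)
            if maf <= maf_min:
                continue
            if var == lead:
                captured.append(var)
                continue
            r2 = ld_r2(dosages[lead].to_numpy(dtype=float), dos)
            if not math.isnan(r2) and r2 >= r2_min:
                captured.append(var)
        return sorted(captured)

    def test_planted_block_exact(self, rng):
        lead = rng.binomial(2, 0.3, 800)
        table = simulate_ld_proxies(lead, n_proxies=5, flip_prob=0.03,
                                    n_independent=5, maf=0.3, seed=5)
        table["rs_lead"] = lead
        cap = ld_block_capture("rs_lead", table, 0.4, 0.01)
        assert sorted(cap.captured) == [f"proxy_{i}" for i in range(5)] + ["rs_lead"]
        assert sorted(cap.captured) == self.brute_force("rs_lead", table, 0.4, 0.01)

    def test_lead_only_vacuous(self, rng):
        import pandas as pd
        table = pd.DataFrame({"rs_lead": rng.binomial(2, 0.3, 100)})
        cap = ld_block_capture("rs_lead", table, 0.4, 0.01)
        assert cap.captured == ["rs_lead"] and cap.capture_fraction == 1.0

    def test_maf_filter_excludes_rare_proxy(self):
        import pandas as pd
        lead = np.array([2] * 5 + [1] * 30 + [0] * 965)
        rare = np.array([1] * 5 + [0] * 995)  # MAF 0.0025, correlated with lead
        table = pd.DataFrame({"rs_lead": lead, "rare": rare})
        cap = ld_block_capture("rs_lead", table, 0.1, 0.01)
        assert "rare" not in cap.captured

    def test_missing_lead_rejected(self, rng):
        import pandas as pd
        with pytest.raises(ValueError):
            ld_block_capture("nope", pd.DataFrame({"a": rng.binomial(2, 0.3, 10)}),
                             0.4, 0.01)


class TestConditionalAssociation:
    def test_collinear_flagged(self, rng):
        x = rng.binomial(2, 0.3, 200).astype(float)
        y = rng.integers(0, 2, 200)
        res = conditional_association(y, x, x)
        assert res.collinear and math.isnan(res.p)

    def test_zero_covariate_reduces_to_unconditional(self, rng):
        x = rng.binomial(2, 0.3, 300).astype(float)
        logit = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.random(300) < logit).astype(float)
        with_cov = conditional_association(y, x, np.zeros(300))
        import statsmodels.api as sm
        f0 = sm.Logit(y, np.ones((300, 1))).fit(disp=0)
        f1 = sm.Logit(y, np.column_stack([np.ones(300), x])).fit(disp=0)
        expected = stats.chi2.sf(2 * (f1.llf - f0.llf), 1)
        assert with_cov.p == pytest.approx(expected, rel=1e-6)

    def test_proxy_null_calibration(self):
        """Conditional p uniform when the covariate is causal and the test SNP a proxy."""
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            causal = r.binomial(2, 0.3, 400).astype(float)
            flip = r.random(400) < 0.1
            proxy = np.where(flip, r.binomial(2, 0.3, 400), causal).astype(float)
            logit = 1 / (1 + np.exp(-(-1.0 + 0.7 * causal)))
            y = (r.random(400) < logit).astype(float)
            res = conditional_association(y, proxy, causal)
            if not math.isnan(res.p):
                ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
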