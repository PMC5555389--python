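"""Clumping, scoring, family selection and interaction models."""

import numpy as np
import pandas as pd
import pytest

from twinherit.grm import GenotypeMatrix
from twinherit.pgs import (ScoreSpec, clump, logistic_interaction_fit, score,
                           select_one_per_family, sex_specific_or)


def _geno(dosages, positions, chrom="1"):
    m = dosages.shape[1]
    snps = pd.DataFrame({"id": [f"s{j}" for j in range(m)], "chrom": chrom,
                         "pos": positions, "a1": "A", "a2": "G"})
    return GenotypeMatrix([f"i{k}" for k in range(len(dosages))], snps,
                          dosages)


def _stats(ids, pos, betas, ps, chrom="1", a1="A", a2="G"):
    return pd.DataFrame({"SNP": ids, "CHR": chrom, "POS": pos,
                         "A1": a1, "A2": a2, "BETA": betas, "P": ps})


class TestClump:
    def test_single_snp_retained(self):
        rng = np.random.default_rng(0)
        G = _geno(rng.binomial(2, 0.3, (50, 1)).astype(float), [1000])
        st = _stats(["s0"], [1000], [0.3], [1e-4])
        assert clump(st, G) == ["s0"]

    def test_distance_rule(self):
        """Two SNPs 100 kb apart: only the smaller p-value survives."""
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, (100, 2)).astype(float)
        G = _geno(d, [100_000, 200_000])
        st = _stats(["s0", "s1"], [100_000, 200_000], [0.3, 0.2],
                    [1e-9, 1e-4])
        assert clump(st, G) == ["s0"]

    def test_distant_uncorrelated_both_survive(self):
        """300 kb apart, r2 ~ 0: both retained."""
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, (500, 2)).astype(float)
        G = _geno(d, [100_000, 400_000])
        assert np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2 < 0.05
        st = _stats(["s0", "s1"], [100_000, 400_000], [0.3, 0.2],
                    [1e-9, 1e-4])
        assert sorted(clump(st, G)) == ["s0", "s1"]

    def test_ld_rule_across_distance(self):
        """Far apart but r2 >= 0.1: weaker SNP removed."""
        rng = np.random.default_rng(3)
        x = rng.binomial(2, 0.3, 500).astype(float)
        y = x.copy()
        flips = rng.random(500) < 0.2
        y[flips] = rng.binomial(2, 0.3, flips.sum())
        G = _geno(np.column_stack([x, y]), [100_000, 900_000])
        st = _stats(["s0", "s1"], [100_000, 900_000], [0.3, 0.2],
                    [1e-9, 1e-4])
        assert clump(st, G) == ["s0"]

    def test_equal_p_ties_break_by_position(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, (100, 2)).astype(float)
        G = _geno(d, [100_000, 150_000])
        st = _stats(["s0", "s1"], [100_000, 150_000], [0.3, 0.2],
                    [1e-5, 1e-5])
        st_rev = st.iloc[::-1].reset_index(drop=True)
        assert clump(st, G) == clump(st_rev, G) == ["s0"]

    def test_no_overlap_signalled(self):
        rng = np.random.default_rng(5)
        G = _geno(rng.binomial(2, 0.3, (50, 1)).astype(float), [1000])
        st = _stats(["absent"], [1000], [0.3], [1e-4])
        with pytest.raises(ValueError, match="no summary-stat SNPs"):
            clump(st, G)


class TestScore:
    def test_hand_arithmetic(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0]])
        G = _geno(d, [1000, 400_000])
        st = _stats(["s0", "s1"], [1000, 400_000], [0.5, -0.25],
                    [1e-4, 1e-3])
        res = score(G, st, ["s0", "s1"], 1.0)
        assert np.allclose(res.raw, [0.5 * 0 - 0.25 * 2, 0.5 * 1 - 0.25 * 1])
        assert res.standardized.mean() == pytest.approx(0.0, abs=1e-10)
        assert res.standardized.std() == pytest.approx(1.0, abs=1e-10)

    def test_zero_betas_zero_scores(self):
        rng = np.random.default_rng(6)
        G = _geno(rng.binomial(2, 0.3, (20, 3)).astype(float),
                  [1, 400_000, 900_000])
        st = _stats(["s0", "s1", "s2"], [1, 400_000, 900_000],
                    [0.0, 0.0, 0.0], [0.1, 0.2, 0.3])
        res = score(G, st, ["s0", "s1", "s2"], 1.0)
        assert np.all(res.raw == 0)

    def test_threshold_filters_snps(self):
        rng = np.random.default_rng(7)
        G = _geno(rng.binomial(2, 0.3, (20, 2)).astype(float), [1, 400_000])
        st = _stats(["s0", "s1"], [1, 400_000], [0.5, 0.2], [1e-9, 0.04])
        res = score(G, st, ["s0", "s1"], 5e-8)
        assert res.snps == ["s0"]
        empty = score(G, st, ["s0", "s1"], 1e-12)
        assert empty.snps == []
        assert np.all(empty.raw == 0)

    def test_ambiguous_alleles_dropped(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.3, (20, 2)).astype(float)
        m = pd.DataFrame({"id": ["s0", "s1"], "chrom": "1",
                          "pos": [1, 400_000], "a1": ["A", "A"],
                          "a2": ["T", "G"]})
        G = GenotypeMatrix([f"i{k}" for k in range(20)], m, d)
        st = _stats(["s0", "s1"], [1, 400_000], [0.5, 0.2], [1e-4, 1e-3],
                    a1=["A", "A"], a2=["T", "G"])
        res = score(G, st, ["s0", "s1"], 1.0)
        assert res.n_dropped_ambiguous == 1
        assert res.snps == ["s1"]


class TestOnePerFamily:
    def _records(self):
        return pd.DataFrame({
            "family_id": ["f1", "f1", "f2", "f2", "f3"],
            "individual_id": ["f1_1", "f1_2", "f2_1", "f2_2", "f3_1"],
            "sex": ["male"] * 5,
        })

    def test_half_of_complete_pairs_kept(self):
        out = select_one_per_family(self._records())
        assert len(out) == 3
        assert out.family_id.is_unique

    def test_singletons_kept(self):
        out = select_one_per_family(self._records())
        assert "f3_1" in set(out.individual_id)

    def test_deterministic_default_and_seeded(self):
        a = select_one_per_family(self._records())
        b = select_one_per_family(self._records())
        pd.testing.assert_frame_equal(a, b)
        c = select_one_per_family(self._records(), seed=3)
        d = select_one_per_family(self._records(), seed=3)
        pd.testing.assert_frame_equal(c, d)


class TestLogistic:
    def test_grid_oracle_equivalence(self):
        """IRLS fit matches a brute-force likelihood grid at n=30."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = (rng.random(30) < 1 / (1 + np.exp(-(0.4 + 0.8 * x)))).astype(float)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        # 2-D grid at 1e-3 resolution around a coarse optimum
        coarse = min(((nll(b0, b1), b0, b1)
                      for b0 in np.arange(-3, 3, 0.1)
                      for b1 in np.arange(-3, 3, 0.1)))
        b0c, b1c = coarse[1], coarse[2]
        best = min(((nll(b0, b1), b0, b1)
                    for b0 in np.arange(b0c - 0.2, b0c + 0.2, 0.001)
                    for b1 in np.arange(b1c - 0.2, b1c + 0.2, 0.001)))
        fit = logistic_interaction_fit(y, x, None,
                                       pd.DataFrame(index=range(30)))
        assert fit.coef["intercept"] == pytest.approx(best[1], abs=2e-3)
        assert fit.coef["pgs"] == pytest.approx(best[2], abs=2e-3)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(10)
        n = 4000
        x = rng.normal(size=n)
        sex = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.2).astype(float)
        cov = pd.DataFrame({"birth_year": rng.normal(size=n)})
        fit = logistic_interaction_fit(y, x, sex, cov)
        assert fit.odds_ratio["pgs"] == pytest.approx(1.0, abs=0.12)

    def test_female_specific_effect_recovered(self):
        """OR 1.26 in women, null in men: interaction OR < 1 and male OR
        near 1 (the study's qualitative pattern)."""
        rng = np.random.default_rng(11)
        ors_f, ors_m = [], []
        for _ in range(5):
            n = 6000
            pgs_v = rng.standard_normal(n)
            sex = rng.integers(0, 2, n).astype(float)
            lin = -1.9 + np.log(1.262) * pgs_v * (1 - sex)
            y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
            cov = pd.DataFrame({"birth_year": rng.normal(size=n),
                                "education_years": rng.normal(11, 3, n)})
            fit = logistic_interaction_fit(y, pgs_v, sex, cov)
            d = sex_specific_or(fit)
            ors_f.append(d["female"]["or"])
            ors_m.append(d["male"]["or"])
        assert np.mean(ors_f) == pytest.approx(1.262, abs=0.08)
        assert np.mean(ors_m) == pytest.approx(1.0, abs=0.08)

    def test_separation_detected(self):
        x = np.concatenate([np.full(15, -2.0), np.full(15, 2.0)])
        y = (x > 0).astype(float)
        with pytest.raises(RuntimeError, match="separation"):
            logistic_interaction_fit(y, x, None,
                                     pd.DataFrame(index=range(30)))


class TestSexSpecificOR:
    def _fit(self, b, g, vb=0.01, vg=0.01, cbg=0.0):
        from twinherit.pgs import LogisticFit
        cov = pd.DataFrame(
            [[vb, cbg], [cbg, vg]],
            index=["pgs", "pgs_x_sex"], columns=["pgs", "pgs_x_sex"])
        return LogisticFit(
            terms=["pgs", "pgs_x_sex"],
            odds_ratio={"pgs": np.exp(b), "pgs_x_sex": np.exp(g)},
            ci_low={}, ci_high={}, p_value={},
            coef={"pgs": b, "pgs_x_sex": g},
            cov_params=cov, n=100, converged=True)

    def test_printed_product(self):
        """Main 1.262 x interaction 0.753 -> male OR 0.950."""
        fit = self._fit(np.log(1.262), np.log(0.753))
        d = sex_specific_or(fit)
        assert round(d["male"]["or"], 3) == 0.950
        assert d["female"]["or"] == pytest.approx(1.262, abs=1e-9)

    def test_unit_interaction(self):
        fit = self._fit(np.log(1.2), 0.0)
        d = sex_specific_or(fit)
        assert d["male"]["or"] == pytest.approx(d["female"]["or"], abs=1e-12)

    def test_all_unit(self):
        fit = self._fit(0.0, 0.0)
        d = sex_specific_or(fit)
        assert d["male"]["or"] == d["female"]["or"] == pytest.approx(1.0)
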