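import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexhet import multitrait_meta as mm


class TestSignedInput:
    def test_female_dominant_positive(self):
        assert mm.signed_input(0.1, 0.5, 0.2) == pytest.approx(0.1)
        assert mm.signed_input(-0.1, 0.5, 0.2) == pytest.approx(0.1)

    def test_male_dominant_negative(self):
        assert mm.signed_input(0.1, 0.2, 0.5) == pytest.approx(-0.1)

    def test_matches_direction_labels(self, rng):
        from sexhet.het_stats import classify_direction
        bf, bm = rng.normal(size=200), rng.normal(size=200)
        bh = rng.normal(size=200)
        signed = mm.signed_input(bh, bf, bm)
        labels = classify_direction(bf, bm)
        assert np.all((signed > 0) == (labels == "female_driven")
                      | (np.abs(bf) == np.abs(bm)))


class TestMetaFixed:
    def test_single_trait_identity(self):
        beta, se, p = mm.meta_fixed([0.3], [0.05])
        assert (beta, se) == (0.3, 0.05)

    def test_two_equal_traits_hand_value(self):
        beta, se, _ = mm.meta_fixed([0.1, 0.1], [0.1, 0.1])
        assert beta == pytest.approx(0.1)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_identity_corr_reproduces_uncorrected(self, rng):
        b = rng.normal(size=4)
        s = rng.uniform(0.05, 0.2, 4)
        assert mm.meta_fixed(b, s) == pytest.approx(
            mm.meta_fixed(b, s, corr=np.eye(4)))

    def test_identical_traits_se_shrinks_sqrt_t(self):
        for t in (2, 5, 10):
            _, se, _ = mm.meta_fixed([0.1] * t, [0.1] * t)
            assert se == pytest.approx(0.1 / np.sqrt(t))

    def test_fully_correlated_traits_do_not_double_count(self):
        """corr = 1 across duplicated traits yields the single-trait SE."""
        corr = np.ones((3, 3))
        beta, se, _ = mm.meta_fixed([0.1] * 3, [0.05] * 3, corr=corr)
        assert se == pytest.approx(0.05, rel=1e-6)
        assert beta == pytest.approx(0.1, rel=1e-6)

    def test_missing_traits_use_available(self):
        beta, se, _ = mm.meta_fixed([0.2, np.nan, 0.2], [0.1, np.nan, 0.1])
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            mm.meta_fixed([np.nan], [np.nan])


class TestOverlapCorr:
    def test_independent_traits_near_zero(self, rng):
        z = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
        r = mm.estimate_overlap_corr(z)
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_duplicated_trait_near_one(self, rng):
        a = rng.normal(size=5000)
        z = pd.DataFrame({"a": a, "b": a})
        r = mm.estimate_overlap_corr(z)
        assert r.loc["a", "b"] == pytest.approx(1.0, abs=0.005)

    @pytest.mark.parametrize("f", [0.25, 0.5, 0.75])
    def test_planted_sample_overlap_recovered(self, f, rng):
        """Traits sharing a fraction f of samples have null z-score
        correlation f (verified against the shared-noise construction)."""
        n = 20_000
        common = rng.normal(size=n)
        z1 = np.sqrt(f) * common + np.sqrt(1 - f) * rng.normal(size=n)
        z2 = np.sqrt(f) * common + np.sqrt(1 - f) * rng.normal(size=n)
        r = mm.estimate_overlap_corr(pd.DataFrame({"a": z1, "b": z2}),
                                     null_band=np.inf)
        assert r.loc["a", "b"] == pytest.approx(f, abs=0.02)

    def test_too_few_null_snps_gives_zero(self, rng):
        z = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        r = mm.estimate_overlap_corr(z, min_snps=100)
        assert r.loc["a", "b"] == 0.0


class TestMetaAnalyse:
    def _wide(self, rng, n=2000, t=3):
        se = pd.DataFrame(rng.uniform(0.05, 0.2, (n, t)),
                          index=[f"rs{i}" for i in range(n)],
                          columns=[f"t{j}" for j in range(t)])
        beta = pd.DataFrame(rng.normal(0, 1, (n, t)) * se.to_numpy(),
                            index=se.index, columns=se.columns)
        pq = pd.DataFrame(rng.uniform(0, 1, (n, t)), index=se.index,
                          columns=se.columns)
        return beta, se, pq

    def test_p_meta_uniform_under_null(self, rng):
        beta, se, pq = self._wide(rng, n=5000)
        out = mm.meta_analyse(beta, se, pq)
        assert stats.kstest(out["p_meta"], "uniform").pvalue > 0.01

    def test_leading_trait_is_min_pq(self, rng):
        beta, se, pq = self._wide(rng, n=100)
        out = mm.meta_analyse(beta, se, pq)
        expected = pq.to_numpy().argmin(axis=1)
        assert list(out["leading_trait"]) == [pq.columns[i] for i in expected]
        np.testing.assert_allclose(out["best_p_q"], pq.to_numpy().min(axis=1))

    def test_matches_per_snp_meta_fixed(self, rng):
        beta, se, pq = self._wide(rng, n=50)
        beta.iloc[0, 1] = np.nan
        se.iloc[0, 1] = np.nan
        corr = np.array([[1, 0.3, 0.1], [0.3, 1, 0.2], [0.1, 0.2, 1]])
        out = mm.meta_analyse(beta, se, pq, corr=pd.DataFrame(
            corr, index=beta.columns, columns=beta.columns))
        for i in range(5):
            b, s, p = mm.meta_fixed(beta.iloc[i], se.iloc[i], corr=corr)
            assert out.at[i, "beta_meta"] == pytest.approx(b)
            assert out.at[i, "se_meta"] == pytest.approx(s)

    def test_overlap_correction_restores_type_i_error(self, rng):
        """With 50% shared samples, uncorrected meta inflates the type-I
        error; the correlated fixed-effects correction restores it."""
        n, f = 30_000, 0.5
        common = rng.normal(size=n)
        z = np.column_stack([
            np.sqrt(f) * common + np.sqrt(1 - f) * rng.normal(size=n),
            np.sqrt(f) * common + np.sqrt(1 - f) * rng.normal(size=n),
        ])
        se = np.full((n, 2), 0.1)
        beta = pd.DataFrame(z * se, index=[f"rs{i}" for i in range(n)],
                            columns=["a", "b"])
        se = pd.DataFrame(se, index=beta.index, columns=beta.columns)
        pq = pd.DataFrame(2 * stats.norm.sf(np.abs(z)), index=beta.index,
                          columns=beta.columns)
        naive = mm.meta_analyse(beta, se, pq)
        rate_naive = (naive["p_meta"] < 0.05).mean()
        corr = mm.estimate_overlap_corr(beta / se)
        fixed = mm.meta_analyse(beta, se, pq, corr=corr)
        rate_fixed = (fixed["p_meta"] < 0.05).mean()
        assert rate_naive > 0.07
        assert rate_fixed == pytest.approx(0.05, abs=0.01)


class TestCombine:
    def test_union_tags_and_set_oracle(self):
        uni = {"t1": pd.DataFrame({"snp_id": ["a", "b"], "p_q": [1e-9, 1e-10]})}
        meta = pd.DataFrame({
            "snp_id": ["a", "c", "d"],
            "p_meta": [1e-9, 1e-12, 0.1],
            "leading_trait": ["t1", "t1", "t1"],
            "best_p_q": [1e-8, 1e-7, 0.5],
        })
        out = mm.combine_uni_multi(uni, meta)
        tags = dict(zip(out["snp_id"], out["provenance"]))
        assert tags == {"a": "both", "b": "univariate_only", "c": "multivariate_only"}
        # best_p_q sharpened by the univariate table where smaller
        best = dict(zip(out["snp_id"], out["best_p_q"]))
        assert best["a"] == pytest.approx(1e-9)
        assert best["b"] == pytest.approx(1e-10)

    def test_maf_filter_applied_to_meta_results(self):
        uni = {}
        meta = pd.DataFrame({
            "snp_id": ["a", "b"], "p_meta": [1e-9, 1e-9],
            "leading_trait": ["t1", "t1"], "best_p_q": [1e-8, 1e-8],
        })
        maf = pd.Series({"a": 0.2, "b": 0.0001})
        out = mm.combine_uni_multi(uni, meta, maf=maf)
        assert list(out["snp_id"]) == ["a"]
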