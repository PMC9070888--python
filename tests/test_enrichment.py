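import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexhet import enrichment as enr

from conftest import make_sumstats


def disease_table(n, n_sig, alpha=0.05, seed=0):
    """Disease stats with exactly n_sig of n SNPs below alpha."""
    rng = np.random.default_rng(seed)
    p = np.concatenate([rng.uniform(0, alpha, n_sig),
                        rng.uniform(alpha, 1, n - n_sig)])
    return make_sumstats(n, seed=seed, pvalue=p)


class TestSignalEnrichment:
    def test_asthma_style_counts(self):
        """1,405 overlapping SNPs with 107 below 0.05: enrichment 7.62%
        against an expected count of 70.25."""
        disease = disease_table(1405, 107)
        res = enr.signal_enrichment(disease["snp_id"], disease)
        assert res.observed_stat == pytest.approx(7.6157, abs=1e-3)
        assert round(res.observed_stat, 2) == 7.62
        assert res.expected_count == pytest.approx(70.25)
        assert res.chi2_p < 0.05

    def test_no_signal_gives_zero_percent(self):
        disease = make_sumstats(50, pvalue=0.5)
        res = enr.signal_enrichment(disease["snp_id"], disease)
        assert res.observed_stat == 0.0
        assert res.expected_stat == 5.0

    def test_expected_count_is_alpha_times_overlap(self, rng):
        for n in (10, 100, 1000):
            disease = disease_table(n, n // 10, seed=n)
            res = enr.signal_enrichment(disease["snp_id"], disease, alpha=0.05)
            assert res.expected_count == pytest.approx(0.05 * res.n_overlap)

    def test_percent_matches_brute_force(self, rng):
        disease = make_sumstats(500, seed=9, pvalue=rng.uniform(0, 1, 500))
        catalog = disease["snp_id"].iloc[::3]
        res = enr.signal_enrichment(catalog, disease)
        sub = disease[disease["snp_id"].isin(set(catalog))]
        assert res.observed_stat == pytest.approx(
            100 * (sub["pvalue"] < 0.05).mean())

    def test_zero_overlap_is_error_naming_disease(self):
        disease = make_sumstats(5)
        with pytest.raises(ValueError, match="asthma"):
            enr.signal_enrichment(["nope"], disease, name="asthma")

    def test_mean_five_percent_and_uniform_chi2_under_independence(self, rng):
        """Catalog membership independent of disease p-values: observed
        percentages average 5% and the analytic chi-square p is uniform."""
        stats_, chi_ps = [], []
        base = make_sumstats(400, seed=1)
        for _ in range(300):
            base["pvalue"] = rng.uniform(0, 1, 400)
            res = enr.signal_enrichment(base["snp_id"], base)
            stats_.append(res.observed_stat)
            chi_ps.append(res.chi2_p)
        assert np.mean(stats_) == pytest.approx(5.0, abs=0.15)
        # the 1-df GOF chi2 p is discrete-ish but close to uniform
        assert stats.kstest(chi_ps, "uniform").pvalue > 1e-4

    def test_empirical_p_against_matched_nulls(self, rng):
        disease = make_sumstats(600, seed=2, pvalue=rng.uniform(0, 1, 600))
        ids = disease["snp_id"].to_numpy()
        # catalog carries planted signal; null sets do not
        disease.loc[:99, "pvalue"] = rng.uniform(0, 0.01, 100)
        catalog = ids[:100]
        nulls = [pd.DataFrame({"snp_id": rng.choice(ids[100:], 100, replace=False)})
                 for _ in range(99)]
        res = enr.signal_enrichment_empirical(catalog, disease, nulls)
        assert res.emp_p == pytest.approx(1 / 100)

    def test_sex_specific_comparison(self, rng):
        disease = make_sumstats(200, seed=3, pvalue=rng.uniform(0, 1, 200))
        catalog = pd.DataFrame({
            "snp_id": disease["snp_id"],
            "direction": np.where(np.arange(200) % 2 == 0, "female_driven",
                                  "male_driven"),
        })
        out = enr.sex_specific_comparison(catalog, disease)
        assert set(out) >= {"female_driven", "male_driven", "chi2_p",
                            "fold_female_vs_male"}
        assert out["chi2_p"] > 0.001  # no planted sex difference


class TestSnpsetOverlap:
    def test_meqtl_style_counts(self):
        """134 of 2,320 catalog SNPs in the target: 5.8% overlap, with the
        unique-probe count deduplicated across SNPs."""
        catalog = [f"rs{i}" for i in range(2320)]
        target = {f"rs{i}" for i in range(134)}
        items = {f"rs{i}": [f"cg{i}", f"cg{i + 1}"] for i in range(134)}
        res = enr.snpset_overlap(catalog, target, items)
        assert res.n_overlap == 134
        assert round(res.observed_stat, 1) == 5.8
        assert res.n_items == 135  # shared probes counted once
        assert res.items_per_snp == (2, 2)

    def test_empty_target(self):
        res = enr.snpset_overlap(["a", "b"], set())
        assert res.observed_stat == 0.0 and res.n_overlap == 0

    def test_matches_brute_force_sets(self, rng):
        catalog = [f"rs{i}" for i in rng.choice(1000, 300, replace=False)]
        target = {f"rs{i}" for i in rng.choice(1000, 200, replace=False)}
        res = enr.snpset_overlap(catalog, target)
        assert res.n_overlap == len(set(catalog) & target)
        assert res.observed_stat == pytest.approx(
            100 * len(set(catalog) & target) / len(catalog))


class TestIntervalOverlap:
    def test_bed_convention(self):
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        cat = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [15, 10, 21]})
        inside = enr.positions_in_intervals(cat["chrom"], cat["pos"], bed)
        assert list(inside) == [True, False, False]

    def test_whole_genome_annotation_gives_100_percent(self):
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10**9]})
        cat = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": [1, 10, 100, 999, 5000],
                            "snp_id": list("abcde")})
        assert enr.interval_overlap(cat, bed).observed_stat == 100.0

    def test_matches_brute_force_scan(self, rng):
        n = 1000
        cat = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], n),
                            "pos": rng.integers(1, 100_000, n)})
        bed = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "start": (s := rng.integers(0, 95_000, 50)),
            "end": s + rng.integers(100, 5000, 50),
        })
        fast = enr.positions_in_intervals(cat["chrom"], cat["pos"], bed)
        slow = [
            ((bed["chrom"] == c) & (bed["start"] < p) & (p <= bed["end"])).any()
            for c, p in zip(cat["chrom"], cat["pos"])
        ]
        assert list(fast) == slow

    def test_chromosome_mismatch_is_error(self):
        bed = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100]})
        cat = pd.DataFrame({"chrom": ["chr1"], "pos": [5]})
        with pytest.raises(ValueError, match="chr1"):
            enr.interval_overlap(cat, bed)

    def test_depletion_and_enrichment_p_complementarity(self, rng):
        """p_ge + p_le >= 1 + 1/(N+1) for the same annotation."""
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50_000]})
        cat = pd.DataFrame({"chrom": ["chr1"] * 50,
                            "pos": rng.integers(1, 100_000, 50)})
        nulls = [pd.DataFrame({"chrom": ["chr1"] * 50,
                               "pos": rng.integers(1, 100_000, 50)})
                 for _ in range(49)]
        res = enr.interval_overlap_empirical(cat, bed, nulls)
        assert res.emp_p + res.emp_p_depletion >= 1 + 1 / 50


class TestConditionalPreqtl:
    def test_empty_subset_is_error(self):
        disease = make_sumstats(10)
        with pytest.raises(ValueError, match="no Pr-eQTL"):
            enr.conditional_preqtl_enrichment(["a"], {"b"}, disease, [[]])

    def test_no_null_sets_is_error(self):
        disease = make_sumstats(10)
        with pytest.raises(ValueError, match="0 available"):
            enr.conditional_preqtl_enrichment(["rs0"], {"rs0"}, disease, [])

    def _simulate(self, rng, sexhet_excess_signal):
        """Disease signal on Pr-eQTLs; optionally extra on sex-het Pr-eQTLs."""
        n = 6000
        ids = np.array([f"rs{i}" for i in range(n)])
        preqtl = set(ids[rng.random(n) < 0.4])
        catalog = ids[:300]
        p = rng.uniform(0, 1, n)
        carrier = np.array([s in preqtl for s in ids]) & (rng.random(n) < 0.15)
        if sexhet_excess_signal:
            extra = np.isin(ids, catalog) & np.array([s in preqtl for s in ids])
            carrier |= extra & (rng.random(n) < 0.35)
        p[carrier] = rng.uniform(0, 0.01, carrier.sum())
        disease = make_sumstats(n, pvalue=p)
        disease["snp_id"] = ids
        hom_pre = [s for s in ids[300:] if s in preqtl]
        nulls = []
        n_sub = len([s for s in catalog if s in preqtl])
        for _ in range(99):
            nulls.append(pd.DataFrame(
                {"snp_id": rng.choice(hom_pre, n_sub, replace=False)}))
        return catalog, preqtl, disease, nulls

    def test_calibrated_when_signal_is_expression_driven(self, rng):
        """If the disease signal rides on Pr-eQTLs generally, the
        conditional enrichment is null-calibrated."""
        hits = 0
        for rep in range(30):
            catalog, preqtl, disease, nulls = self._simulate(rng, False)
            res = enr.conditional_preqtl_enrichment(catalog, preqtl, disease, nulls)
            hits += res.emp_p < 0.05
        assert hits <= 6  # ~1.5 expected at alpha 0.05

    def test_powered_for_sexhet_specific_excess(self, rng):
        hits = 0
        for rep in range(10):
            catalog, preqtl, disease, nulls = self._simulate(rng, True)
            res = enr.conditional_preqtl_enrichment(catalog, preqtl, disease, nulls)
            hits += res.emp_p < 0.05
        assert hits >= 8
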