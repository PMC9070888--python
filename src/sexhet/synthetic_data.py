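"""Synthetic GWAS inputs with planted ground truth.

Generates every input the pipeline consumes — sex-stratified summary
statistics for several biometric traits, combined-sex disease statistics,
gene models, pLI scores, GMT gene sets, regulatory interval sets, meQTL and
Pr-eQTL maps, and a block-diagonal LD reference — at desk scale, so every
stage is testable with known truth and no downloads.

Model.  Each SNP has a minor allele frequency drawn from a Beta distribution,
and per-stratum standard errors follow the standardized-trait relation
se = 1/sqrt(2 maf (1-maf) n_stratum); effects live on the z scale and are
converted through that se, which keeps runtime flat in sample size (no
genotypes are simulated).  A fraction of SNPs carries a shared (sex-
homogeneous) association signal; a smaller planted fraction is sex-
heterogeneous, with the female-male difference set to a target |dbeta|/SE
drawn from a grid and realized through one of three mechanisms (effect in one
sex only / opposite directions / same direction, different magnitude) in
proportions mirroring the discovered catalog.  LD is block-exchangeable:
within a block of consecutive SNPs the effect-estimate noise is correlated
with coefficient sqrt(r2), so pairwise estimate correlation matches the
block r^2 used by the LD provider.

All generators are deterministic given the master seed; independent
sub-streams are derived per product so regenerating one input does not
perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gene_annotation import annotate_snps, gene_list
from .ld_clump import LDProvider
from .sumstats_io import SUMSTATS_COLUMNS, AnnotationTables

__all__ = ["SimConfig", "simulate_sumstats", "simulate_disease",
           "simulate_annotations", "replace"]

_P_FLOOR = 1e-300

MECHANISMS = ("one_sex_only", "opposite_direction", "magnitude_difference")


@dataclass
class SimConfig:
    """Scenario parameters; defaults give a desk-scale study emulating the
    sex-stratified biometric-trait setting."""

    n_snps: int = 100_000
    n_traits: int = 3
    n_female: int = 170_000          # consortium-scale stratum sizes
    n_male: int = 150_000
    n_chrom: int = 10
    snp_spacing_bp: int = 5_000
    ld_block_size: int = 10
    ld_r2_within: float = 0.5
    maf_beta_a: float = 1.0          # maf ~ 0.5 * Beta(a, b), floored
    maf_beta_b: float = 3.0
    maf_floor: float = 0.0002
    ambiguous_fraction: float = 0.01  # A/T-C/G SNPs (dropped at harmonization)
    orientation_shuffle: float = 0.2  # male rows written on the flipped allele

    assoc_fraction: float = 0.05     # sex-homogeneous polygenic signal
    assoc_z_sd: float = 4.0
    sexhet_fraction: float = 0.003
    zdiff_grid: tuple = (4.0, 5.0, 6.0)
    mechanism_mix: tuple = (0.668, 0.326, 0.006)
    sexhet_min_maf: float = 0.01     # catalog SNPs are common variants

    disease_pleiotropy_fraction: float = 0.1
    disease_signal_z: float = 3.0

    gene_length_bp: int = 20_000
    gene_gap_bp: int = 80_000
    n_exons: int = 5
    exon_length_bp: int = 1_000
    utr_length_bp: int = 500
    pli_constrained_fraction: float = 0.2
    meqtl_rate: float = 0.05
    meqtl_excess: float = 1.2
    preqtl_rate: float = 0.17
    preqtl_excess: float = 1.28       # sex-het vs sex-hom overlap 21.8% vs 17%
    n_tissues: int = 49
    n_brain_tissues: int = 13
    regulatory_coverages: tuple = (0.02, 0.05, 0.1, 0.2, 0.3)
    gene_set_size: int = 300
    n_random_gene_sets: int = 5
    gene_set_fe: float = 3.0
    assoc_gene_top_frac: float = 0.10  # |marginal beta| rank tail keying the
    assoc_gene_z_min: float = 4.0      # association gene-set layer (fallback)

    seed: int = 0

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


_NONAMBIG = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
             ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIG = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _two_sided_p(z):
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)


def _layout(config: SimConfig, rng) -> pd.DataFrame:
    """SNP map: ids, positions, blocks, maf, alleles, planted truth labels."""
    n = config.n_snps
    per_chrom = int(np.ceil(n / config.n_chrom))
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in range(n)], dtype=object)
    pos = np.array([(i % per_chrom + 1) * config.snp_spacing_bp for i in range(n)])
    block = np.arange(n) // config.ld_block_size
    maf = np.maximum(0.5 * rng.beta(config.maf_beta_a, config.maf_beta_b, n),
                     config.maf_floor)

    amb = rng.random(n) < config.ambiguous_fraction
    pair_idx = rng.integers(len(_NONAMBIG), size=n)
    ea = np.array([_NONAMBIG[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_NONAMBIG[i][1] for i in pair_idx], dtype=object)
    amb_idx = rng.integers(len(_AMBIG), size=n)
    ea[amb] = [_AMBIG[i][0] for i in amb_idx[np.flatnonzero(amb)]]
    oa[amb] = [_AMBIG[i][1] for i in amb_idx[np.flatnonzero(amb)]]

    truth = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": chrom, "pos": pos, "block": block, "maf": maf,
        "effect_allele": ea, "other_allele": oa, "ambiguous": amb,
    })

    # sex-homogeneous polygenic signal (shared across traits and sexes)
    assoc = rng.random(n) < config.assoc_fraction
    assoc_z = np.where(assoc, rng.normal(0.0, config.assoc_z_sd, n), 0.0)
    truth["assoc_z"] = assoc_z

    # planted sex-heterogeneous SNPs: common, non-ambiguous
    plantable = np.flatnonzero((maf >= config.sexhet_min_maf) & ~amb)
    n_het = int(round(config.sexhet_fraction * n))
    het_idx = rng.choice(plantable, size=min(n_het, len(plantable)), replace=False)
    is_het = np.zeros(n, dtype=bool)
    is_het[het_idx] = True
    truth["is_sexhet"] = is_het
    zdiff = np.zeros(n)
    zdiff[het_idx] = rng.choice(np.asarray(config.zdiff_grid, float), size=len(het_idx))
    truth["zdiff"] = zdiff
    mech = np.full(n, "", dtype=object)
    mech[het_idx] = rng.choice(MECHANISMS, size=len(het_idx),
                               p=np.asarray(config.mechanism_mix) / sum(config.mechanism_mix))
    truth["mechanism"] = mech
    truth["female_larger"] = rng.random(n) < 0.5
    return truth


def _stratum_table(truth, beta, se, n_samples, flip=None) -> pd.DataFrame:
    eaf = truth["maf"].to_numpy().copy()
    ea = truth["effect_allele"].to_numpy(object).copy()
    oa = truth["other_allele"].to_numpy(object).copy()
    beta = np.asarray(beta, float).copy()
    if flip is not None:
        # write these rows on the opposite allele orientation
        beta[flip] = -beta[flip]
        eaf[flip] = 1.0 - eaf[flip]
        ea[flip], oa[flip] = oa[flip].copy(), ea[flip].copy()
    return pd.DataFrame({
        "snp_id": truth["snp_id"], "chrom": truth["chrom"], "pos": truth["pos"],
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": _two_sided_p(beta / se),
        "n": np.full(len(truth), n_samples, dtype=int),
    })[SUMSTATS_COLUMNS]


def _block_noise(rng, block, corr):
    """Unit-variance noise, exchangeable within LD blocks with correlation corr."""
    own = rng.normal(size=len(block))
    if corr <= 0:
        return own
    n_blocks = int(block.max()) + 1
    common = rng.normal(size=n_blocks)
    return np.sqrt(corr) * common[block] + np.sqrt(1.0 - corr) * own


def simulate_sumstats(config: SimConfig):
    """Generate per-trait female and male summary statistics plus the truth
    table.  Returns ``(tables, truth)`` with ``tables[trait] = (female_df,
    male_df)``."""
    rng = config.rng(1)
    truth = _layout(config, rng)
    maf = truth["maf"].to_numpy()
    block = truth["block"].to_numpy()
    se_f = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_female)
    se_m = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_male)
    se_comb = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * (config.n_female + config.n_male))
    se_diff = np.sqrt(se_f**2 + se_m**2)
    noise_corr = np.sqrt(config.ld_r2_within)

    shared = truth["assoc_z"].to_numpy() * se_comb
    delta = truth["zdiff"].to_numpy() * se_diff
    mech = truth["mechanism"].to_numpy(object)
    fem_larger = truth["female_larger"].to_numpy()

    big = np.where(mech == "one_sex_only", delta,
                   np.where(mech == "opposite_direction", delta / 2.0, 1.5 * delta))
    small = np.where(mech == "one_sex_only", 0.0,
                     np.where(mech == "opposite_direction", -delta / 2.0, 0.5 * delta))
    het_f = np.where(fem_larger, big, small)
    het_m = np.where(fem_larger, small, big)

    tables = {}
    for t in range(config.n_traits):
        trng = config.rng(100 + t)
        bf = shared + het_f + se_f * _block_noise(trng, block, noise_corr)
        bm = shared + het_m + se_m * _block_noise(trng, block, noise_corr)
        flip = trng.random(config.n_snps) < config.orientation_shuffle
        female = _stratum_table(truth, bf, se_f, config.n_female)
        male = _stratum_table(truth, bm, se_m, config.n_male, flip=flip)
        tables[f"trait{t + 1}"] = (female, male)
    truth = truth.copy()
    truth["se_f"], truth["se_m"], truth["se_comb"] = se_f, se_m, se_comb
    # true combined-sex marginal effect on the z scale (inverse-variance
    # weights), the quantity the matched-null rank matching conditions on
    wf, wm = 1.0 / se_f**2, 1.0 / se_m**2
    truth["marginal_z"] = ((wf * (shared + het_f) + wm * (shared + het_m))
                           / (wf + wm)) / se_comb
    return tables, truth


def simulate_disease(config: SimConfig, truth: pd.DataFrame, *,
                     pleiotropy_fraction: float | None = None,
                     control_fraction: float = 0.0,
                     signal_z: float | None = None,
                     restrict_to=None, stream: int = 2) -> pd.DataFrame:
    """Combined-sex disease summary statistics.

    A ``pleiotropy_fraction`` of the planted sex-het SNPs (and a
    ``control_fraction`` of the remaining SNPs) receives a non-null
    association with |z| centred on ``signal_z``; every other SNP is null
    with Uniform(0,1) p.  ``restrict_to`` limits signal carriers to a SNP id
    subset (e.g. Pr-eQTLs) for the conditional-enrichment scenarios.
    """
    if pleiotropy_fraction is None:
        pleiotropy_fraction = config.disease_pleiotropy_fraction
    if signal_z is None:
        signal_z = config.disease_signal_z
    rng = config.rng(stream)
    n = len(truth)
    het = truth["is_sexhet"].to_numpy()
    carriers = (het & (rng.random(n) < pleiotropy_fraction)) | (
        ~het & (rng.random(n) < control_fraction))
    if restrict_to is not None:
        carriers &= truth["snp_id"].isin(set(restrict_to)).to_numpy()
    z = rng.normal(0.0, 1.0, n)
    z[carriers] += signal_z * rng.choice([-1.0, 1.0], size=int(carriers.sum()))
    p = _two_sided_p(z)
    p[~carriers] = rng.uniform(0.0, 1.0, int((~carriers).sum()))
    p = np.clip(p, _P_FLOOR, 1.0)
    se = truth["se_comb"].to_numpy() if "se_comb" in truth else np.full(n, 0.01)
    beta = stats.norm.isf(p / 2.0) * np.sign(z) * se
    out = pd.DataFrame({
        "snp_id": truth["snp_id"], "chrom": truth["chrom"], "pos": truth["pos"],
        "effect_allele": truth["effect_allele"], "other_allele": truth["other_allele"],
        "eaf": truth["maf"], "beta": beta, "se": se, "pvalue": p,
        "n": np.full(n, config.n_female + config.n_male, dtype=int),
    })[SUMSTATS_COLUMNS]
    out.attrs["carriers"] = truth.loc[carriers, "snp_id"].tolist()
    return out


def _gene_models(config: SimConfig, truth: pd.DataFrame, rng):
    """Genes laid along each chromosome with exponentially distributed
    intergenic gaps (mean ``gene_gap_bp``), so flank distances vary the way
    they do in real gene deserts vs dense regions."""
    genes, exons, utrs = [], [], []
    for chrom, sub in truth.groupby("chrom", sort=False):
        chrom_len = int(sub["pos"].max()) + config.snp_spacing_bp
        cursor, g = 1, 0
        while cursor + config.gene_length_bp < chrom_len:
            start = cursor
            end = start + config.gene_length_bp - 1
            g += 1
            gid = f"{chrom}_G{g}"
            genes.append((gid, chrom, start, end, "+" if g % 2 == 0 else "-"))
            utrs.append((gid, start, start + config.utr_length_bp - 1))
            utrs.append((gid, end - config.utr_length_bp + 1, end))
            step = config.gene_length_bp // config.n_exons
            for e in range(config.n_exons):
                es = start + e * step
                exons.append((gid, es, es + config.exon_length_bp - 1))
            cursor = end + 1 + int(rng.exponential(config.gene_gap_bp))
    genes = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    exons = pd.DataFrame(exons, columns=["gene_id", "start", "end"])
    utrs = pd.DataFrame(utrs, columns=["gene_id", "start", "end"])
    return genes, exons, utrs


def _boosted_set(rng, all_genes, boosted_genes, size, fe) -> list[str]:
    """Gene set where boosted genes are ``fe`` times more likely members;
    expected size ~ ``size``."""
    q0 = min(1.0, size / len(all_genes))
    boosted = set(boosted_genes)
    probs = np.array([min(1.0, q0 * fe) if g in boosted else q0 for g in all_genes])
    member = rng.random(len(all_genes)) < probs
    return [g for g, m in zip(all_genes, member) if m]


def simulate_annotations(config: SimConfig, truth: pd.DataFrame):
    """Generate AnnotationTables and the block-diagonal LDProvider.

    Gene sets include random sets, a set preferentially containing genes near
    planted sex-het SNPs (the sex-het-specific layer) and a set keyed on
    genes near large sex-homogeneous association signals (the trait-
    association layer); their relative membership boost is
    ``config.gene_set_fe``.
    """
    rng = config.rng(3)
    genes, exons, utrs = _gene_models(config, truth, config.rng(30))
    all_genes = genes["gene_id"].tolist()

    constrained = rng.random(len(all_genes)) < config.pli_constrained_fraction
    pli_vals = np.where(constrained, rng.beta(10, 0.5, len(all_genes)),
                        rng.beta(0.5, 10, len(all_genes)))
    pli = pd.Series(pli_vals, index=all_genes, name="pli")

    het_snps = truth[truth["is_sexhet"]]
    het_genes = gene_list(annotate_snps(het_snps, genes, exons, utrs)) if len(het_snps) else []
    # the trait-association layer is keyed on top-ranked |combined-sex
    # marginal beta| — the exact covariate matched nulls preserve — so the
    # permutation layer can calibrate it out, sex-het or not
    if "marginal_z" in truth:
        marg_beta = np.abs(truth["marginal_z"] * truth["se_comb"])
        thr = np.quantile(marg_beta, 1.0 - config.assoc_gene_top_frac)
        assoc_snps = truth[marg_beta >= thr]
    else:
        assoc_snps = truth[np.abs(truth["assoc_z"]) >= config.assoc_gene_z_min]
    assoc_genes = gene_list(annotate_snps(assoc_snps, genes, exons, utrs)) if len(assoc_snps) else []

    gene_sets = {
        "sexhet_specific": _boosted_set(rng, all_genes, het_genes,
                                        config.gene_set_size, config.gene_set_fe),
        "assoc_driven": _boosted_set(rng, all_genes, assoc_genes,
                                     config.gene_set_size, config.gene_set_fe),
    }
    for k in range(config.n_random_gene_sets):
        gene_sets[f"random_{k + 1}"] = list(
            rng.choice(all_genes, size=min(config.gene_set_size, len(all_genes) // 2),
                       replace=False))

    # regulatory interval sets: non-overlapping slots, a `coverage` fraction on
    intervals = {}
    slot = 2_000
    for c in config.regulatory_coverages:
        rows = []
        for chrom, sub in truth.groupby("chrom", sort=False):
            chrom_len = int(sub["pos"].max()) + config.snp_spacing_bp
            n_slots = chrom_len // slot
            on = rng.random(n_slots) < c
            for s in np.flatnonzero(on):
                rows.append((chrom, s * slot, (s + 1) * slot, f"cov{c}"))
        intervals[f"regulatory_cov{c}"] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name"])

    het = truth["is_sexhet"].to_numpy()
    snp_ids = truth["snp_id"].to_numpy(object)

    def qtl_map(rate, excess, item_prefix, tissues, max_items, stream):
        qrng = config.rng(stream)
        prob = np.where(het, min(1.0, rate * excess), rate)
        member = qrng.random(len(truth)) < prob
        rows = []
        for i in np.flatnonzero(member):
            k = min(int(qrng.geometric(0.5)), max_items)
            for _ in range(k):
                item = f"{item_prefix}{qrng.integers(1, 20 * len(truth))}"
                tissue = tissues[qrng.integers(len(tissues))]
                rows.append((snp_ids[i], item, 10.0 ** -qrng.uniform(10, 30), tissue))
        return pd.DataFrame(rows, columns=["snp_id", item_prefix, "p", "tissue"]).rename(
            columns={item_prefix: "cpg" if item_prefix == "cg" else "egene"})

    meqtl = qtl_map(config.meqtl_rate, config.meqtl_excess, "cg",
                    ["cord_blood", "maternal_blood"], 25, stream=4)
    tissue_names = ([f"brain_{i + 1}" for i in range(config.n_brain_tissues)]
                    + [f"tissue_{i + 1}" for i in range(config.n_tissues - config.n_brain_tissues)])
    preqtl = qtl_map(config.preqtl_rate, config.preqtl_excess, "ENSG",
                     tissue_names, 29, stream=5)

    tables = AnnotationTables(gene_models=genes, exons=exons, utrs=utrs, pli=pli,
                              gene_sets=gene_sets, intervals=intervals,
                              meqtl=meqtl, preqtl=preqtl)
    ld = LDProvider.from_blocks(dict(zip(snp_ids, truth["block"])), config.ld_r2_within)
    return tables, ld
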