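"""Overlap-based enrichment statistics for the sex-het catalog.

Three families of statistics, all compared against matched sex-homogeneous
permutation nulls:

* association-signal enrichment: among catalog SNPs present in a disease or
  trait GWAS, the percentage with P < alpha versus the null expectation of
  100*alpha (analytic 1-df chi-square goodness of fit on counts, plus a
  rank-based empirical p over matched null sets);
* SNP-set overlap: percentage of the catalog intersecting a target SNP set
  (meQTLs at P < 1e-14, Pr-eQTLs, hormone-responsive-gene SNPs), with unique
  item counts (CpG probes, eGenes) when a SNP->item multimap is supplied;
* genomic-interval overlap: percentage of catalog SNPs falling inside a named
  annotation (BED convention: 0-based half-open), tested in both the
  enrichment and depletion directions.

The conditional Pr-eQTL analysis re-runs the signal enrichment on the
catalog's Pr-eQTL subset against nulls drawn only from sex-homogeneous
Pr-eQTLs, separating sex-heterogeneity from expression-regulatory function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matched_null import empirical_p

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    name: str
    n_overlap: int
    observed_stat: float            # percent scale
    expected_stat: float            # percent scale
    expected_count: float | None = None
    observed_count: int | None = None
    chi2_p: float | None = None
    emp_p: float | None = None
    emp_p_depletion: float | None = None
    n_items: int | None = None      # unique probes / eGenes
    items_per_snp: tuple | None = None
    extras: dict = field(default_factory=dict)


def signal_enrichment(catalog_snps, disease: pd.DataFrame, alpha: float = 0.05,
                      name: str = "disease", method: str = "chi2") -> EnrichmentResult:
    """Percent of catalog SNPs with disease association P < alpha.

    ``disease`` is a combined-sex summary-statistics table.  The expected
    count is alpha times the overlap; the analytic p is a 1-df chi-square
    goodness-of-fit test of the observed count against it (``method="fisher"``
    switches to a binomial-style Fisher exact on the 2x1 margin for small
    overlaps).
    """
    catalog_snps = set(catalog_snps)
    sub = disease[disease["snp_id"].isin(catalog_snps)]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no overlap between catalog and {name!r} summary statistics")
    obs = int((sub["pvalue"] < alpha).sum())
    exp = alpha * n
    observed_pct = 100.0 * obs / n
    if method == "chi2":
        chi2 = (obs - exp) ** 2 / exp + ((n - obs) - (n - exp)) ** 2 / (n - exp)
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "fisher":
        p = float(stats.binomtest(obs, n, alpha).pvalue)
    else:
        raise ValueError("method must be 'chi2' or 'fisher'")
    return EnrichmentResult(name=name, n_overlap=n, observed_stat=observed_pct,
                            expected_stat=100.0 * alpha, expected_count=exp,
                            observed_count=obs, chi2_p=p)


def signal_enrichment_empirical(catalog_snps, disease: pd.DataFrame,
                                null_sets: list, alpha: float = 0.05,
                                name: str = "disease") -> EnrichmentResult:
    """Signal enrichment with an empirical p against matched null sets."""
    res = signal_enrichment(catalog_snps, disease, alpha=alpha, name=name)
    null_stats = []
    for s in null_sets:
        snps = s["snp_id"] if isinstance(s, pd.DataFrame) else s
        try:
            null_stats.append(signal_enrichment(snps, disease, alpha=alpha).observed_stat)
        except ValueError:
            continue
    if null_stats:
        res.emp_p = empirical_p(res.observed_stat, null_stats, tail="ge")
        res.extras["null_mean"] = float(np.mean(null_stats))
    return res


def sex_specific_comparison(catalog: pd.DataFrame, disease: pd.DataFrame,
                            alpha: float = 0.05) -> dict:
    """Compare female-driven vs male-driven subsets' signal enrichment.

    Returns each subset's enrichment, the female/male fold ratio of enriched
    percentages, and a 2x2 chi-square p-value contrasting the subsets.
    """
    out = {}
    counts = {}
    for direction in ("female_driven", "male_driven"):
        snps = catalog.loc[catalog["direction"] == direction, "snp_id"]
        res = signal_enrichment(snps, disease, alpha=alpha, name=direction)
        out[direction] = res
        counts[direction] = (res.observed_count, res.n_overlap - res.observed_count)
    table = np.array([counts["female_driven"], counts["male_driven"]])
    if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        out["chi2_p"] = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        out["chi2_p"] = np.nan
    f, m = out["female_driven"].observed_stat, out["male_driven"].observed_stat
    out["fold_female_vs_male"] = f / m if m > 0 else np.inf
    return out


def snpset_overlap(catalog_snps, target_snps, per_snp_items: dict | None = None,
                   name: str = "snpset") -> EnrichmentResult:
    """Overlap between the catalog and a target SNP id set.

    The observed statistic is the percent of catalog SNPs in the target set.
    With ``per_snp_items`` (SNP -> iterable of CpG probes or eGenes), the
    unique item count over the overlapping SNPs and the per-SNP item-count
    range are reported; a SNP counts once regardless of item multiplicity.
    """
    catalog_snps = list(dict.fromkeys(catalog_snps))
    target = set(target_snps)
    hits = [s for s in catalog_snps if s in target]
    pct = 100.0 * len(hits) / len(catalog_snps) if catalog_snps else 0.0
    res = EnrichmentResult(name=name, n_overlap=len(hits), observed_stat=pct,
                           expected_stat=np.nan)
    if per_snp_items is not None:
        items = set()
        counts = []
        for s in hits:
            snp_items = set(per_snp_items.get(s, ()))
            items |= snp_items
            counts.append(len(snp_items))
        res.n_items = len(items)
        res.items_per_snp = (min(counts), max(counts)) if counts else (0, 0)
    return res


def snpset_overlap_empirical(catalog_snps, target_snps, null_sets: list,
                             per_snp_items: dict | None = None,
                             name: str = "snpset") -> EnrichmentResult:
    """SNP-set overlap with empirical p-values for the overlap percentage and
    (when a multimap is given) the unique item count."""
    res = snpset_overlap(catalog_snps, target_snps, per_snp_items, name=name)
    null_pct, null_items = [], []
    for s in null_sets:
        snps = s["snp_id"] if isinstance(s, pd.DataFrame) else s
        r = snpset_overlap(snps, target_snps, per_snp_items)
        null_pct.append(r.observed_stat)
        if per_snp_items is not None:
            null_items.append(r.n_items)
    res.emp_p = empirical_p(res.observed_stat, null_pct, tail="ge")
    res.extras["null_median_pct"] = float(np.median(null_pct))
    if null_items:
        res.extras["emp_p_items"] = empirical_p(res.n_items, null_items, tail="ge")
        res.extras["null_median_items"] = float(np.median(null_items))
    return res


# ---------------------------------------------------------------------------
# interval overlap


def _merged_intervals(bed: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for chrom, sub in bed.groupby("chrom"):
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def positions_in_intervals(chroms, positions, bed: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each 1-based position fall inside >= 1 BED interval
    (0-based half-open, so pos is inside [start, end] iff start < pos <= end)."""
    merged = _merged_intervals(bed)
    chroms = np.asarray(chroms, object)
    positions = np.asarray(positions, int)
    out = np.zeros(len(positions), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        mask = chroms == chrom
        pos0 = positions[mask] - 1  # 0-based coordinate of the SNP base
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        out[mask] = inside
    return out


def interval_overlap(catalog: pd.DataFrame, bed: pd.DataFrame,
                     name: str = "annotation") -> EnrichmentResult:
    """Percent of catalog SNPs (chrom, pos columns) inside the annotation."""
    cat_chroms = set(catalog["chrom"])
    bed_chroms = set(bed["chrom"])
    if not (cat_chroms & bed_chroms):
        raise ValueError(
            f"chromosome-name mismatch for {name!r}: catalog has "
            f"{sorted(cat_chroms)}, annotation has {sorted(bed_chroms)}")
    inside = positions_in_intervals(catalog["chrom"], catalog["pos"], bed)
    return EnrichmentResult(name=name, n_overlap=int(inside.sum()),
                            observed_stat=100.0 * inside.mean(),
                            expected_stat=np.nan)


def interval_overlap_empirical(catalog: pd.DataFrame, bed: pd.DataFrame,
                               null_sets_positions: list[pd.DataFrame],
                               name: str = "annotation") -> EnrichmentResult:
    """Interval overlap with empirical p in both directions (enrichment and
    depletion).  Each null set must carry chrom/pos for its SNPs."""
    res = interval_overlap(catalog, bed, name=name)
    null_stats = [interval_overlap(s, bed).observed_stat for s in null_sets_positions]
    res.emp_p = empirical_p(res.observed_stat, null_stats, tail="ge")
    res.emp_p_depletion = empirical_p(res.observed_stat, null_stats, tail="le")
    res.extras["null_median_pct"] = float(np.median(null_stats))
    return res


def conditional_preqtl_enrichment(catalog_snps, preqtl_snps, disease: pd.DataFrame,
                                  preqtl_null_sets: list, alpha: float = 0.05,
                                  name: str = "disease") -> EnrichmentResult:
    """Signal enrichment restricted to the catalog's Pr-eQTL subset, against
    nulls drawn only from sex-homogeneous Pr-eQTLs.

    ``preqtl_null_sets`` must already be sampled from an eligibility pool
    intersected with Pr-eQTL membership (see matched_null).  Distinguishes a
    sex-het-specific disease signal from one carried by expression-regulatory
    variants generally.
    """
    preqtl_snps = set(preqtl_snps)
    subset = [s for s in catalog_snps if s in preqtl_snps]
    if not subset:
        raise ValueError("catalog has no Pr-eQTL SNPs")
    if not preqtl_null_sets:
        raise ValueError("no Pr-eQTL-restricted null sets supplied (0 available)")
    return signal_enrichment_empirical(subset, disease, preqtl_null_sets,
                                       alpha=alpha, name=name)


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten EnrichmentResults into a TSV-ready table (Table 2/4 layout)."""
    rows = []
    for r in results:
        rows.append({
            "name": r.name, "n_overlap": r.n_overlap,
            "observed_pct": r.observed_stat, "expected_pct": r.expected_stat,
            "expected_count": r.expected_count, "observed_count": r.observed_count,
            "chi2_p": r.chi2_p, "emp_p": r.emp_p,
            "emp_p_depletion": r.emp_p_depletion,
            "n_items": r.n_items,
            "items_per_snp": (f"{r.items_per_snp[0]}-{r.items_per_snp[1]}"
                              if r.items_per_snp else None),
        })
    return pd.DataFrame(rows)
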