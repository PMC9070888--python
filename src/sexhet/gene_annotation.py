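"""SNP-to-gene mapping, the nearest-gene distance diagnostic, and constraint
(pLI) enrichment of the mapped gene list.

A SNP inside a gene body is assigned that gene with a genic class (priority
splicing > utr > exonic > intronic; "splicing" means within 2 bp of an
exon-intron boundary).  An intergenic SNP is assigned its nearest gene only
when the distance to the gene boundary is at most 25 kb; beyond that no gene
is assigned, which keeps noise out of downstream gene-based analyses.  The
cutoff is supported by the gene_A/gene_B diagnostic: the nearest flanking
gene (gene_A) vastly outnumbers the second flank (gene_B) within 25 kb, and
the excess decays with distance.

Distances are measured SNP-to-nearest transcript boundary (start or end,
whichever is closer), strand-ignorant.  When gene models carry no exon
substructure, genic SNPs are classed "intronic" (the class does not affect
gene assignment).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

GENIC_PRIORITY = ["splicing", "utr", "exonic", "intronic"]
DEFAULT_CUTOFF_BP = 25_000
SPLICE_WINDOW_BP = 2
DISTANCE_BINS_KB = [(0, 25), (25, 50), (50, 100), (100, 200), (200, 500), (500, 2000)]


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for gid, s, e in zip(sub["gene_id"], sub["start"], sub["end"]):
            t.addi(int(s), int(e) + 1, gid)  # 1-based inclusive -> half-open
        trees[chrom] = t
    return trees


def _sub_intervals(df: pd.DataFrame | None) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    if df is not None:
        for gid, s, e in zip(df["gene_id"], df["start"], df["end"]):
            out.setdefault(gid, []).append((int(s), int(e)))
    return out


def _genic_class(pos: int, exons: list[tuple[int, int]],
                 utrs: list[tuple[int, int]]) -> str:
    for s, e in utrs:
        if s <= pos <= e:
            return "utr"
    if not exons:
        return "intronic"
    in_exon = any(s <= pos <= e for s, e in exons)
    # splice sites: within SPLICE_WINDOW_BP of an internal exon boundary
    bounds = sorted(b for s, e in exons for b in (s, e))
    internal = bounds[1:-1]
    if any(abs(pos - b) <= SPLICE_WINDOW_BP for b in internal):
        return "splicing"
    return "exonic" if in_exon else "intronic"


def annotate_snps(snps: pd.DataFrame, genes: pd.DataFrame,
                  exons: pd.DataFrame | None = None,
                  utrs: pd.DataFrame | None = None,
                  cutoff_bp: int = DEFAULT_CUTOFF_BP) -> pd.DataFrame:
    """Assign genes to SNPs (snp_id, chrom, pos columns).

    Returns one row per SNP: genic_class, gene (None when unassigned),
    distance_bp (0 for genic SNPs), and for intergenic SNPs the two flanking
    genes gene_a/gene_b with their distances (diagnostic-only; only gene_a
    within the cutoff is ever *assigned*).
    """
    trees = _gene_trees(genes)
    exon_iv = _sub_intervals(exons)
    utr_iv = _sub_intervals(utrs)
    by_chrom = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in genes.groupby("chrom")
    }
    rows = []
    for snp, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        pos = int(pos)
        hits = trees.get(chrom, IntervalTree())[pos]
        if hits:
            best_class, best_gene = None, None
            for iv in hits:
                gid = iv.data
                cls = _genic_class(pos, exon_iv.get(gid, []), utr_iv.get(gid, []))
                if best_class is None or GENIC_PRIORITY.index(cls) < GENIC_PRIORITY.index(best_class):
                    best_class, best_gene = cls, gid
            if len(hits) > 1:
                logger.debug("annotate_snps: %s overlaps %d genes; kept %s",
                             snp, len(hits), best_gene)
            rows.append((snp, best_class, best_gene, 0, None, np.nan, None, np.nan))
            continue
        sub = by_chrom.get(chrom)
        if sub is None or sub.empty:
            rows.append((snp, "intergenic", None, np.nan, None, np.nan, None, np.nan))
            continue
        starts = sub["start"].to_numpy()
        i = int(np.searchsorted(starts, pos))
        flanks = []
        for j in (i - 1, i):
            if 0 <= j < len(sub):
                s, e = int(sub.at[j, "start"]), int(sub.at[j, "end"])
                d = s - pos if pos < s else (pos - e if pos > e else 0)
                flanks.append((d, sub.at[j, "gene_id"]))
        flanks.sort()
        gene_a = flanks[0] if flanks else (np.nan, None)
        gene_b = flanks[1] if len(flanks) > 1 else (np.nan, None)
        assigned = gene_a[1] if flanks and gene_a[0] <= cutoff_bp else None
        rows.append((snp, "intergenic", assigned,
                     gene_a[0] if assigned else np.nan,
                     gene_a[1], gene_a[0], gene_b[1], gene_b[0]))
    return pd.DataFrame(rows, columns=[
        "snp_id", "genic_class", "gene", "distance_bp",
        "gene_a", "distance_a", "gene_b", "distance_b"])


def gene_list(assignments: pd.DataFrame) -> list[str]:
    """Unique assigned genes, in first-appearance order."""
    return list(dict.fromkeys(g for g in assignments["gene"] if g is not None))


def distance_ratio_diagnostic(assignments: pd.DataFrame,
                              bins_kb=DISTANCE_BINS_KB) -> pd.DataFrame:
    """Per-distance-bin ratio of nearest-gene (gene_A) to second-flank
    (gene_B) SNP counts, over intergenic SNPs with both flanks known."""
    inter = assignments[(assignments["genic_class"] == "intergenic")
                        & assignments["gene_a"].notna()
                        & assignments["gene_b"].notna()]
    da = inter["distance_a"].to_numpy(float)
    db = inter["distance_b"].to_numpy(float)
    rows = []
    for lo, hi in bins_kb:
        na = int(((da >= lo * 1000) & (da < hi * 1000)).sum())
        nb = int(((db >= lo * 1000) & (db < hi * 1000)).sum())
        rows.append((f"{lo}-{hi}kb", na, nb, na / nb if nb else np.nan))
    return pd.DataFrame(rows, columns=["bin", "n_gene_a", "n_gene_b", "ratio"])


def constraint_enrichment(genes: list[str], pli: pd.Series,
                          reference_proportions: dict[str, float]) -> pd.DataFrame:
    """Constraint profile of a gene list against reference bin proportions.

    ``reference_proportions`` maps bins ("pli>0.9", "pli<0.1") to the expected
    fraction in a reference gene census.  Each bin's observed fraction is
    tested with a two-sided exact binomial test.
    """
    scores = pli.reindex([g for g in genes if g in pli.index]).dropna()
    if scores.empty:
        raise ValueError("no pLI coverage for the supplied gene list")
    n = len(scores)
    rows = []
    for bin_name, ref in reference_proportions.items():
        if bin_name == "pli>0.9":
            k = int((scores > 0.9).sum())
        elif bin_name == "pli<0.1":
            k = int((scores < 0.1).sum())
        else:
            raise ValueError(f"unknown pLI bin {bin_name!r}")
        p = float(stats.binomtest(k, n, ref).pvalue)
        rows.append((bin_name, n, k, k / n, ref, p))
    return pd.DataFrame(rows, columns=["bin", "n_genes", "n_in_bin",
                                       "observed_fraction", "reference_fraction",
                                       "binom_p"])
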