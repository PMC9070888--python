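"""Matched sex-homogeneous permutation nulls and empirical p-values.

The sex-het catalog is an ascertained SNP set: its members are common and
carry strong combined-sex marginal effects, so naive random SNP sets are the
wrong null.  Instead, for each catalog SNP a sex-homogeneous SNP is drawn
that matches it on

* minor allele frequency, within +/-0.001 when the catalog SNP has
  MAF < 0.01 and +/-0.02 otherwise, and
* combined-sex marginal effect, within +/-75 positions in the pool ranked by
  the inverse-variance meta-analysed female+male beta of the leading trait,

from a pool that excludes the catalog SNPs themselves and every SNP in LD
(r^2 > 0.2) with them.  Sampling is uniform over eligible matches, without
replacement within a set; SNPs may recur across the (default 1,000) sets.
An entry with no eligible match has its tolerances doubled up to three times
and finally falls back to the nearest eligible neighbor; every relaxation is
flagged on the emitted set.

Empirical p-values are rank-based: empP = (1 + #{null >= observed}) / (N + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld_clump import LDProvider

logger = logging.getLogger(__name__)

MAF_TOL_RARE = 0.001   # catalog maf < 0.01
MAF_TOL_COMMON = 0.02  # catalog maf >= 0.01 (boundary uses the common rule)
RANK_WINDOW = 75
LD_EXCLUDE_R2 = 0.2


@dataclass
class MatchingIndex:
    """Per-pool-SNP matching covariates and eligibility.

    ``table`` columns: snp_id, maf, rank (ordinal 1..pool size by ascending
    combined-sex marginal beta), eligible (not sex-het, not in LD r^2 > 0.2
    with any sex-het SNP).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.sort_values("rank").reset_index(drop=True)
        self.table = t
        self._maf = t["maf"].to_numpy(float)
        self._eligible = t["eligible"].to_numpy(bool)
        self._snp = t["snp_id"].to_numpy(object)
        self._rank_of = dict(zip(t["snp_id"], t["rank"].astype(int)))
        self._maf_of = dict(zip(t["snp_id"], t["maf"]))

    @property
    def pool_size(self) -> int:
        return len(self.table)


def combined_marginal(paired: pd.DataFrame) -> np.ndarray:
    """Combined-sex marginal effect: inverse-variance meta of the female and
    male betas per SNP."""
    wf = 1.0 / paired["se_f"].to_numpy(float) ** 2
    wm = 1.0 / paired["se_m"].to_numpy(float) ** 2
    return (wf * paired["beta_f"].to_numpy(float) +
            wm * paired["beta_m"].to_numpy(float)) / (wf + wm)


def build_index(pool: pd.DataFrame, catalog_snps, ld: LDProvider,
                ld_exclude_r2: float = LD_EXCLUDE_R2) -> MatchingIndex:
    """Build the matching index from a harmonized pool (one trait).

    ``pool`` must contain every catalog SNP (hard error otherwise).  Ranks are
    ordinal positions in the pool sorted by combined-sex marginal beta; ties
    broken by snp_id for determinism.
    """
    catalog_snps = set(catalog_snps)
    missing = catalog_snps - set(pool["snp_id"])
    if missing:
        raise ValueError(f"pool is missing {len(missing)} catalog SNPs")
    marg = combined_marginal(pool)
    order = np.lexsort((pool["snp_id"].to_numpy(object), marg))
    rank = np.empty(len(pool), dtype=int)
    rank[order] = np.arange(1, len(pool) + 1)

    ineligible = set(catalog_snps)
    for snp in catalog_snps:
        ineligible.update(ld.neighbors(snp, np.nextafter(ld_exclude_r2, 1.0)))
    table = pd.DataFrame({
        "snp_id": pool["snp_id"].to_numpy(object),
        "maf": pool["maf"].to_numpy(float),
        "rank": rank,
        "eligible": [s not in ineligible for s in pool["snp_id"]],
    })
    return MatchingIndex(table)


def maf_tolerance(maf: float) -> float:
    """Tolerance rule: +/-0.001 below MAF 0.01, +/-0.02 at or above it."""
    return MAF_TOL_RARE if maf < 0.01 else MAF_TOL_COMMON


def _candidates(index: MatchingIndex, rank: int, maf: float,
                rank_window: int, maf_tol: float) -> np.ndarray:
    lo = max(rank - rank_window - 1, 0)
    hi = min(rank + rank_window, index.pool_size)
    window = np.arange(lo, hi)
    mask = index._eligible[lo:hi] & (np.abs(index._maf[lo:hi] - maf) <= maf_tol)
    return window[mask]


class MatchedNullSampler:
    """Draws matched sex-homogeneous SNP sets, one SNP per catalog entry.

    ``indexes`` is either a single :class:`MatchingIndex` (one reference
    pool) or a dict keyed by trait when per-leading-trait pools are used, in
    which case the catalog must carry a ``leading_trait`` column.
    """

    def __init__(self, indexes, catalog: pd.DataFrame,
                 rank_window: int = RANK_WINDOW, max_relax: int = 3):
        self.multi = isinstance(indexes, dict)
        self.indexes = indexes
        self.rank_window = rank_window
        self.max_relax = max_relax
        self.catalog = catalog.reset_index(drop=True)
        self._entries = []  # (index, rank, maf, candidate arrays per relax level)
        for _, row in self.catalog.iterrows():
            idx = indexes[row["leading_trait"]] if self.multi else indexes
            snp = row["snp_id"]
            rank, maf = idx._rank_of[snp], idx._maf_of[snp]
            base_tol = maf_tolerance(maf)
            levels = []
            for k in range(max_relax + 1):
                levels.append(_candidates(idx, rank, maf,
                                          rank_window * 2**k, base_tol * 2**k))
            self._entries.append((idx, rank, maf, base_tol, levels))

    def sample(self, seed) -> pd.DataFrame:
        """Draw one matched set; reproducible from ``seed``.

        Returns one row per catalog entry: snp_id (the null SNP), catalog
        SNP, maf/rank deltas and the relaxation level used (0 = strict
        tolerances; -1 marks the nearest-neighbor fallback).
        """
        rng = np.random.default_rng(seed)
        used: dict[int, set[int]] = {}
        rows = []
        for (idx, rank, maf, base_tol, levels), cat_snp in zip(
                self._entries, self.catalog["snp_id"]):
            uset = used.setdefault(id(idx), set())
            choice, level = None, None
            for k, cand in enumerate(levels):
                avail = cand[[c not in uset for c in cand]] if uset else cand
                if len(avail):
                    choice = int(avail[rng.integers(len(avail))])
                    level = k
                    break
            if choice is None:
                # nearest eligible unused neighbor in scaled (rank, maf) distance
                free = np.flatnonzero(idx._eligible)
                free = free[[c not in uset for c in free]]
                if len(free) == 0:
                    raise RuntimeError("matched-null pool exhausted")
                d = (np.abs(free + 1 - rank) / self.rank_window
                     + np.abs(idx._maf[free] - maf) / base_tol)
                choice, level = int(free[int(np.argmin(d))]), -1
                logger.warning("sample_matched_set: nearest-neighbor fallback for %s", cat_snp)
            elif level > 0:
                logger.warning("sample_matched_set: tolerances doubled x%d for %s",
                               level, cat_snp)
            uset.add(choice)
            rows.append((idx._snp[choice], cat_snp,
                         idx._maf[choice] - maf, (choice + 1) - rank, level))
        out = pd.DataFrame(rows, columns=["snp_id", "catalog_snp", "maf_delta",
                                          "rank_delta", "relax_level"])
        out.attrs["seed"] = seed
        return out


def sample_matched_set(index, catalog: pd.DataFrame, seed,
                       rank_window: int = RANK_WINDOW) -> pd.DataFrame:
    """One-shot convenience wrapper around :class:`MatchedNullSampler`."""
    return MatchedNullSampler(index, catalog, rank_window=rank_window).sample(seed)


def sample_matched_sets(index, catalog: pd.DataFrame, n_sets: int = 1000,
                        seed: int = 0, rank_window: int = RANK_WINDOW) -> list[pd.DataFrame]:
    """Draw ``n_sets`` matched sets with independent per-set RNG streams
    derived deterministically from one master seed."""
    sampler = MatchedNullSampler(index, catalog, rank_window=rank_window)
    children = np.random.SeedSequence(seed).spawn(n_sets)
    return [sampler.sample(child) for child in children]


def empirical_p(observed: float, null_values, tail: str = "ge") -> float:
    """Rank-based empirical p-value: (1 + #{null beyond observed}) / (N + 1).

    ``tail="ge"`` counts null values >= observed (enrichment); ``tail="le"``
    counts null values <= observed (depletion).
    """
    null_values = np.asarray(null_values, float)
    if null_values.size < 1:
        raise ValueError("need at least one null value")
    if tail == "ge":
        k = int(np.sum(null_values >= observed))
    elif tail == "le":
        k = int(np.sum(null_values <= observed))
    else:
        raise ValueError("tail must be 'ge' or 'le'")
    return (1 + k) / (null_values.size + 1)


def matching_diagnostics(catalog_maf, null_sets: list[pd.DataFrame],
                         pool_maf) -> pd.DataFrame:
    """MAF-distribution diagnostic: medians and KS distances of catalog vs
    pool vs sampled null sets (null SNP MAF = catalog MAF + maf_delta)."""
    catalog_maf = np.asarray(catalog_maf, float)
    pool_maf = np.asarray(pool_maf, float)
    null_mafs = [catalog_maf + s["maf_delta"].to_numpy(float) for s in null_sets]
    all_null = np.concatenate(null_mafs)
    rows = [
        ("catalog", np.median(catalog_maf), 0.0),
        ("pool", np.median(pool_maf),
         stats.ks_2samp(catalog_maf, pool_maf).statistic),
        ("null_sets", np.median(all_null),
         stats.ks_2samp(catalog_maf, all_null).statistic),
    ]
    return pd.DataFrame(rows, columns=["collection", "median_maf", "ks_vs_catalog"])
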