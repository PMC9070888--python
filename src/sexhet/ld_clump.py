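"""Greedy LD clumping of candidate SNPs to an independent tag set.

Candidates are visited in order of ascending best Cochran's Q p-value; a SNP
is kept iff its r^2 with every already-kept SNP is below the threshold
(default 0.2).  Ties on p are broken by (chrom, pos, snp_id) for determinism.
SNPs absent from the LD reference are treated as independent and kept, with a
logged count.  Clumping is genome-wide: cross-chromosome (cross-block) r^2 is
defined as 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LDProvider:
    """Pairwise r^2 lookup backed by a sparse pair map or LD blocks.

    Symmetric; r^2(a, a) = 1; unknown or cross-block pairs have r^2 = 0.
    """

    def __init__(self, pairs: dict[str, dict[str, float]] | None = None):
        self._pairs = pairs or {}

    @classmethod
    def from_pair_table(cls, df: pd.DataFrame) -> "LDProvider":
        """Build from a (snp_a, snp_b, r2) long table."""
        pairs: dict[str, dict[str, float]] = {}
        for a, b, r2 in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2].astype(float)):
            pairs.setdefault(a, {})[b] = r2
            pairs.setdefault(b, {})[a] = r2
        return cls(pairs)

    @classmethod
    def from_pair_file(cls, path) -> "LDProvider":
        return cls.from_pair_table(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_blocks(cls, block_of: dict[str, int], r2_within: float) -> "LDProvider":
        """Block-diagonal LD: constant r2 within a block, 0 across blocks."""
        members: dict[int, list[str]] = {}
        for snp, blk in block_of.items():
            members.setdefault(blk, []).append(snp)
        pairs: dict[str, dict[str, float]] = {}
        for blk, snps in members.items():
            for a in snps:
                pairs[a] = {b: r2_within for b in snps if b != a}
        return cls(pairs)

    def knows(self, snp: str) -> bool:
        return snp in self._pairs

    def lookup(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._pairs.get(snp_a, {}).get(snp_b, 0.0)

    def neighbors(self, snp: str, r2_min: float) -> list[str]:
        """All SNPs with r^2 >= r2_min with ``snp`` (excluding itself)."""
        return [b for b, r2 in self._pairs.get(snp, {}).items() if r2 >= r2_min]


def clump(candidates: pd.DataFrame, ld: LDProvider,
          r2_threshold: float = 0.2) -> pd.DataFrame:
    """Greedy clumping on best_p_q; returns the independent catalog.

    ``candidates`` needs columns snp_id and best_p_q; chrom/pos are used for
    deterministic tie-breaking when present, and any further columns are
    carried through.  The output is sorted by best_p_q ascending and satisfies
    pairwise r^2 < r2_threshold.
    """
    if candidates.empty:
        raise ValueError("no candidate SNPs to clump")
    df = candidates.copy()
    sort_cols = ["best_p_q"] + [c for c in ("chrom", "pos", "snp_id") if c in df.columns]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    excluded: set[str] = set()
    keep_rows = []
    n_unknown = 0
    for i, snp in enumerate(df["snp_id"]):
        if snp in excluded:
            continue
        if not ld.knows(snp):
            n_unknown += 1
        keep_rows.append(i)
        for nb in ld.neighbors(snp, r2_threshold):
            excluded.add(nb)
    if n_unknown:
        logger.warning("clump: %d kept SNPs absent from the LD reference "
                       "(treated as independent)", n_unknown)
    return df.iloc[keep_rows].reset_index(drop=True)
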