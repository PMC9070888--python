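"""Gene-set overrepresentation analysis (ORA) with permutation calibration.

For a gene list L drawn from a universe U and a gene set S, the expected
overlap is |S∩U| * |L| / |U| and the fold enrichment FE = observed/expected.
Significance is the two-sided Fisher exact test on the 2x2 membership table
(one-tailed hypergeometric available via ``alternative``), with
Benjamini-Hochberg FDR across sets.

Gene lists derived from trait-associated SNPs are enriched in many sets for
reasons unrelated to sex heterogeneity (allele-frequency and effect-size
ascertainment), so a second, permutation layer re-runs the ORA on gene lists
built from matched sex-homogeneous SNP sets and reports a rank-based
empirical p per set: the ge tail of the observed FE for overrepresented sets
and the le tail for underrepresented ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matched_null import empirical_p

logger = logging.getLogger(__name__)


@dataclass
class OraRow:
    set_name: str
    n_reference: int       # set genes within the universe
    n_observed: int        # list genes in the set
    n_expected: float
    fold_enrichment: float
    direction: str         # "+" iff observed > expected
    p_value: float


def ora_test(gene_list, gene_set, universe, alternative: str = "two-sided") -> OraRow:
    """Test one gene set against one gene list.

    ``gene_list`` must be a subset of ``universe`` (genes outside it are
    dropped with a warning, mirroring the removal of unmapped genes before
    testing).  ``alternative`` is passed to Fisher's exact test ("greater"
    gives the one-tailed hypergeometric).
    """
    universe = set(universe)
    lst = set(gene_list)
    outside = lst - universe
    if outside:
        logger.warning("ora_test: dropping %d list genes outside the universe", len(outside))
        lst &= universe
    if not lst:
        raise ValueError("empty gene list after restricting to the universe")
    ref = set(gene_set) & universe
    n_obs = len(lst & ref)
    n_exp = len(ref) * len(lst) / len(universe)
    table = [[n_obs, len(ref) - n_obs],
             [len(lst) - n_obs, len(universe) - len(ref) - len(lst) + n_obs]]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    return OraRow(
        set_name="", n_reference=len(ref), n_observed=n_obs, n_expected=n_exp,
        fold_enrichment=n_obs / n_exp if n_exp > 0 else np.nan,
        direction="+" if n_obs > n_exp else "-", p_value=p)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ora_collection(gene_list, gene_sets: dict, universe,
                   alternative: str = "two-sided") -> pd.DataFrame:
    """Run ora_test over a GMT collection; adds BH-FDR across sets."""
    rows = []
    for name, genes in gene_sets.items():
        row = ora_test(gene_list, genes, universe, alternative=alternative)
        row.set_name = name
        rows.append(row)
    df = pd.DataFrame([vars(r) for r in rows])
    df["fdr"] = fdr_bh(df["p_value"])
    return df


def ora_empirical(observed: pd.DataFrame, permuted_gene_lists: list,
                  gene_sets: dict, universe) -> pd.DataFrame:
    """Attach empirical p-values to an observed ORA table.

    Each permuted list (typically the genes mapped to one matched
    sex-homogeneous SNP set) is scored with the same FE statistic; emp_p per
    set is the rank of the observed FE among permuted FEs, toward the
    direction of the observed effect.
    """
    if not permuted_gene_lists:
        raise ValueError("need at least one permuted gene list")
    universe = set(universe)
    perm_fe = {name: [] for name in gene_sets}
    for lst in permuted_gene_lists:
        lst = set(lst) & universe
        for name, genes in gene_sets.items():
            ref = set(genes) & universe
            n_exp = len(ref) * len(lst) / len(universe)
            fe = (len(lst & ref) / n_exp) if n_exp > 0 else np.nan
            perm_fe[name].append(fe)
    out = observed.copy()
    emp = []
    for _, row in out.iterrows():
        tail = "ge" if row["direction"] == "+" else "le"
        emp.append(empirical_p(row["fold_enrichment"], perm_fe[row["set_name"]], tail=tail))
    out["emp_p"] = emp
    return out
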