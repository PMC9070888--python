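"""Per-trait two-stratum sex-heterogeneity statistics.

For a SNP with female and male effect estimates (beta_f, se_f) and
(beta_m, se_m), heterogeneity between the sexes is tested with Cochran's Q,

    Q = (beta_f - beta_m)^2 / (se_f^2 + se_m^2),   Q ~ chi^2 with 1 df,

equivalently the signed heterogeneity Z-score

    Z_het = (beta_f - beta_m) / sqrt(se_f^2 + se_m^2),   Q = Z_het^2.

Z_het is converted back onto an effect scale (for downstream cross-trait
meta-analysis) using the allele frequency p and total sample size n:

    beta_het = Z_het / sqrt(2 p (1-p) (n + Z_het^2))
    se_het   = 1     / sqrt(2 p (1-p) (n + Z_het^2))

so that beta_het / se_het == Z_het identically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1DF_MEDIAN = 0.4549364231195728

FEMALE_DRIVEN = "female_driven"
MALE_DRIVEN = "male_driven"


def _check_se(*ses):
    for se in ses:
        if np.any(np.asarray(se) <= 0):
            raise ValueError("standard errors must be positive")


def z_het(beta_f, se_f, beta_m, se_m):
    """Signed heterogeneity Z-score (female minus male, in units of the
    pooled standard error)."""
    _check_se(se_f, se_m)
    beta_f, se_f = np.asarray(beta_f, float), np.asarray(se_f, float)
    beta_m, se_m = np.asarray(beta_m, float), np.asarray(se_m, float)
    return (beta_f - beta_m) / np.sqrt(se_f**2 + se_m**2)


def cochran_q(beta_f, se_f, beta_m, se_m):
    """Cochran's Q for two strata and its upper-tail chi^2(1 df) p-value."""
    z = z_het(beta_f, se_f, beta_m, se_m)
    q = z**2
    return q, stats.chi2.sf(q, df=1)


def zhet_to_effect(z, p, n):
    """Convert a heterogeneity Z-score to (beta_het, se_het).

    ``p`` is the allele frequency in (0,1) and ``n`` the total (female + male)
    sample size.  The ratio beta_het/se_het recovers ``z`` exactly.
    """
    z = np.asarray(z, float)
    p = np.asarray(p, float)
    n = np.asarray(n, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    se = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * (n + z**2))
    return z * se, se


def classify_direction(beta_f, beta_m):
    """female_driven iff |beta_f| > |beta_m|, else male_driven.

    Exact ties are assigned male_driven deterministically (and logged); they
    have measure zero on real data.
    """
    beta_f = np.asarray(beta_f, float)
    beta_m = np.asarray(beta_m, float)
    fem = np.abs(beta_f) > np.abs(beta_m)
    n_ties = int(np.sum(np.abs(beta_f) == np.abs(beta_m)))
    if n_ties:
        logger.warning("classify_direction: %d exact |beta| ties assigned male_driven", n_ties)
    out = np.where(fem, FEMALE_DRIVEN, MALE_DRIVEN)
    return out if out.ndim else out.item()


def classify_mechanism(p_f, p_m, beta_f, beta_m, alpha: float = 0.05):
    """Classify how the sex difference arises at per-sex nominal level alpha.

    one_sex_only: exactly one stratum significant; opposite_direction: both
    significant with opposite signs; magnitude_difference: both significant,
    same sign; undetermined: neither stratum nominal (rare for catalog SNPs).
    """
    p_f, p_m = np.asarray(p_f, float), np.asarray(p_m, float)
    beta_f, beta_m = np.asarray(beta_f, float), np.asarray(beta_m, float)
    sig_f, sig_m = p_f < alpha, p_m < alpha
    out = np.full(np.broadcast(p_f, p_m).shape, "undetermined", dtype=object)
    one = sig_f ^ sig_m
    both = sig_f & sig_m
    out[one] = "one_sex_only"
    out[both & (np.sign(beta_f) != np.sign(beta_m))] = "opposite_direction"
    out[both & (np.sign(beta_f) == np.sign(beta_m))] = "magnitude_difference"
    return out if out.ndim else out.item()


def genomic_inflation(pvalues=None, chi2=None) -> float:
    """Genomic inflation factor lambda = median(chi^2) / 0.4549364.

    Provide either p-values (converted via the inverse upper-tail chi^2(1),
    computed from log(p) to stay finite below 1e-300) or chi-square values.
    """
    if chi2 is None:
        if pvalues is None:
            raise ValueError("provide pvalues or chi2")
        p = np.asarray(pvalues, float)
        if p.size == 0:
            raise ValueError("empty input")
        # chi2(1) quantile via the normal: chi2 = Phi^{-1}(p/2)^2, in log space
        chi2 = stats.norm.isf(np.exp(np.log(p) - np.log(2.0))) ** 2
    chi2 = np.asarray(chi2, float)
    if chi2.size == 0:
        raise ValueError("empty input")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def het_table(paired: pd.DataFrame) -> pd.DataFrame:
    """Compute the full per-SNP heterogeneity record table for one trait.

    ``paired`` is a harmonized female/male table (see
    :func:`sexhet.sumstats_io.harmonize_pair`).  The allele frequency entering
    the effect-scale conversion is the harmonized maf.
    """
    z = z_het(paired["beta_f"], paired["se_f"], paired["beta_m"], paired["se_m"])
    q = z**2
    p_q = stats.chi2.sf(q, df=1)
    beta_het, se_het = zhet_to_effect(z, paired["maf"], paired["n_total"])
    out = paired[["snp_id", "chrom", "pos", "maf", "n_total",
                  "beta_f", "se_f", "p_f", "beta_m", "se_m", "p_m"]].copy()
    out["q_stat"] = q
    out["p_q"] = p_q
    out["z_het"] = z
    out["beta_het"] = beta_het
    out["se_het"] = se_het
    out["direction"] = classify_direction(paired["beta_f"], paired["beta_m"])
    return out


def select_trait_sexhet(paired: pd.DataFrame, p_threshold: float = 5e-8,
                        maf_min: float = 0.001) -> pd.DataFrame:
    """Trait-specific sex-het SNPs: P_Q < p_threshold and MAF >= maf_min."""
    het = het_table(paired)
    keep = (het["p_q"] < p_threshold) & (het["maf"] >= maf_min)
    return het[keep].reset_index(drop=True)


def write_het_table(het: pd.DataFrame, path) -> None:
    het.to_csv(path, sep="\t", index=False)
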