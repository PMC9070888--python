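"""Cross-trait fixed-effects meta-analysis of heterogeneity effects.

Per-trait heterogeneity effects (beta_het, se_het) are combined across traits
by inverse-variance fixed-effects meta-analysis.  Because the contributing
GWAS may share samples, an optional sample-overlap correction is applied in
the correlated fixed-effects (Lin-Sullivan) form: with per-trait standard
errors s and an estimated trait-by-trait correlation matrix R of null
z-scores, the effect covariance is Sigma_ij = R_ij s_i s_j and

    beta_meta = (1' Sigma^-1 b) / (1' Sigma^-1 1),
    se_meta   = 1 / sqrt(1' Sigma^-1 1).

R is estimated from the z-score correlation over SNPs where both traits are
null (|z| below a band, default 1), which is how sample overlap manifests in
summary statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def signed_input(beta_het, beta_f, beta_m):
    """Orient the heterogeneity effect for meta-analysis.

    The magnitude is |beta_het|; the sign is positive when the female effect
    dominates (|beta_f| > |beta_m|) and negative otherwise, so that traits
    where the same sex drives the difference reinforce each other.
    """
    beta_het = np.asarray(beta_het, float)
    sign = np.where(np.abs(np.asarray(beta_f, float)) > np.abs(np.asarray(beta_m, float)),
                    1.0, -1.0)
    return sign * np.abs(beta_het)


def _truncated_corr(rho: float, c: float, nodes: int = 48) -> float:
    """Pearson correlation of a standard bivariate normal with correlation
    ``rho`` doubly truncated to the box |x| < c, |y| < c (Gauss-Legendre)."""
    x, wx = np.polynomial.legendre.leggauss(nodes)
    x = x * c
    wx = wx * c
    xx, yy = np.meshgrid(x, x)
    w2 = np.outer(wx, wx)
    det = 1.0 - rho**2
    dens = np.exp(-(xx**2 - 2 * rho * xx * yy + yy**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det))
    mass = np.sum(w2 * dens)
    m11 = np.sum(w2 * xx * yy * dens) / mass
    m2 = np.sum(w2 * xx**2 * dens) / mass
    return m11 / m2


def _detruncate_corr(r_obs: float, c: float) -> float:
    """Invert the attenuation that truncating to |z| < c imposes on a
    bivariate-normal correlation (e.g. at c=1 a true rho of 0.5 yields an
    in-band Pearson r of only ~0.15)."""
    if not np.isfinite(c):
        return r_obs
    from scipy.optimize import brentq

    lim = _truncated_corr(0.999, c)
    if abs(r_obs) >= lim:
        return float(np.sign(r_obs) * 0.999)
    return float(brentq(lambda rho: _truncated_corr(rho, c) - r_obs,
                        -0.999, 0.999, xtol=1e-6))


def estimate_overlap_corr(z: pd.DataFrame, null_band: float = 1.0,
                          min_snps: int = 100, debias: bool = True) -> pd.DataFrame:
    """Estimate the trait-by-trait null z-score correlation matrix.

    ``z`` is a SNP x trait DataFrame of signed heterogeneity z-scores (NaN for
    missing SNPs).  For each trait pair, Pearson correlation is computed over
    SNPs where both |z| < null_band — the band keeps genuinely associated
    SNPs out of the estimate — and then corrected for the attenuation the
    band truncation induces (``debias``).  Pairs with fewer than ``min_snps``
    in-band SNPs get correlation 0 with a warning.
    """
    traits = list(z.columns)
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    r = np.eye(len(traits))
    vals = z.to_numpy(float)
    in_band = np.abs(vals) < null_band
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            mask = in_band[:, i] & in_band[:, j]
            mask &= np.isfinite(vals[:, i]) & np.isfinite(vals[:, j])
            if mask.sum() < min_snps:
                logger.warning("estimate_overlap_corr: only %d null SNPs for (%s, %s); using 0",
                               int(mask.sum()), traits[i], traits[j])
                continue
            rij = np.corrcoef(vals[mask, i], vals[mask, j])[0, 1]
            if debias:
                rij = _detruncate_corr(rij, null_band)
            r[i, j] = r[j, i] = rij
    return pd.DataFrame(r, index=traits, columns=traits)


def meta_fixed(betas, ses, corr=None):
    """Fixed-effects meta-analysis of one SNP's per-trait effects.

    Without ``corr``: classical inverse-variance weighting.  With ``corr`` (a
    trait x trait correlation matrix aligned with the inputs): the correlated
    fixed-effects estimate; a singular covariance falls back to the
    uncorrected path with a warning.  Returns (beta_meta, se_meta, p_meta).
    """
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    ok = np.isfinite(b) & np.isfinite(s)
    if not ok.any():
        raise ValueError("no trait with data for this SNP")
    b, s = b[ok], s[ok]
    if corr is not None:
        r = np.asarray(corr, float)[np.ix_(ok, ok)]
        try:
            rinv = np.linalg.inv(r)
        except np.linalg.LinAlgError:
            # e.g. perfectly duplicated traits: the pseudo-inverse gives the
            # correct limiting estimate (no double counting)
            logger.warning("meta_fixed: singular correlation matrix; using pseudo-inverse")
            rinv = np.linalg.pinv(r)
        if rinv is not None:
            u = 1.0 / s
            denom = u @ rinv @ u
            if denom <= 0:
                logger.warning("meta_fixed: non-positive precision; using uncorrected weights")
            else:
                beta = (u @ rinv @ (b / s)) / denom
                se = 1.0 / np.sqrt(denom)
                return beta, se, 2.0 * stats.norm.sf(abs(beta / se))
    w = 1.0 / s**2
    beta = np.sum(w * b) / np.sum(w)
    se = 1.0 / np.sqrt(np.sum(w))
    return beta, se, 2.0 * stats.norm.sf(abs(beta / se))


def meta_analyse(beta: pd.DataFrame, se: pd.DataFrame, p_q: pd.DataFrame,
                 corr: pd.DataFrame | None = None) -> pd.DataFrame:
    """Meta-analyse all SNPs at once (SNP x trait wide tables, NaN = missing).

    Grouped by missingness pattern so the correlated path inverts each trait
    subset's correlation matrix once.  Returns a MetaHetRecord table with
    beta_meta, se_meta, p_meta, n_traits_contributing, leading_trait (minimum
    per-trait P_Q among contributing traits) and best_p_q.
    """
    traits = list(beta.columns)
    b = beta.to_numpy(float)
    s = se.to_numpy(float)
    pq = p_q.reindex(columns=traits).to_numpy(float)
    present = np.isfinite(b) & np.isfinite(s)
    if not present.any(axis=1).all():
        raise ValueError("some SNPs have no trait with data")

    n_snp = b.shape[0]
    beta_meta = np.empty(n_snp)
    se_meta = np.empty(n_snp)
    r_full = None if corr is None else corr.loc[traits, traits].to_numpy(float)

    patterns = {}
    for i, row in enumerate(map(tuple, present)):
        patterns.setdefault(row, []).append(i)
    for pat, idx in patterns.items():
        idx = np.asarray(idx)
        cols = np.flatnonzero(pat)
        bs, ss = b[np.ix_(idx, cols)], s[np.ix_(idx, cols)]
        rinv = None
        if r_full is not None:
            r_sub = r_full[np.ix_(cols, cols)]
            try:
                rinv = np.linalg.inv(r_sub)
            except np.linalg.LinAlgError:
                logger.warning("meta_analyse: singular correlation for a trait subset; "
                               "using pseudo-inverse")
                rinv = np.linalg.pinv(r_sub)
        if rinv is None:
            w = 1.0 / ss**2
            beta_meta[idx] = np.sum(w * bs, axis=1) / np.sum(w, axis=1)
            se_meta[idx] = 1.0 / np.sqrt(np.sum(w, axis=1))
        else:
            u = 1.0 / ss
            denom = np.einsum("ni,ij,nj->n", u, rinv, u)
            num = np.einsum("ni,ij,nj->n", u, rinv, bs / ss)
            bad = denom <= 0
            if bad.any():
                logger.warning("meta_analyse: %d SNPs with non-positive precision; "
                               "uncorrected weights used", int(bad.sum()))
                w = 1.0 / ss[bad]**2
                num[bad] = np.sum(w * bs[bad], axis=1)
                denom[bad] = np.sum(w, axis=1)
            beta_meta[idx] = num / denom
            se_meta[idx] = 1.0 / np.sqrt(denom)

    z = beta_meta / se_meta
    p_meta = 2.0 * stats.norm.sf(np.abs(z))
    pq_masked = np.where(present & np.isfinite(pq), pq, np.inf)
    lead_idx = np.argmin(pq_masked, axis=1)
    return pd.DataFrame({
        "snp_id": beta.index,
        "beta_meta": beta_meta,
        "se_meta": se_meta,
        "p_meta": p_meta,
        "n_traits_contributing": present.sum(axis=1),
        "leading_trait": [traits[i] for i in lead_idx],
        "best_p_q": pq_masked[np.arange(n_snp), lead_idx],
    }).reset_index(drop=True)


def combine_uni_multi(univariate: dict[str, pd.DataFrame], meta: pd.DataFrame,
                      het_tables: dict[str, pd.DataFrame] | None = None,
                      p_threshold: float = 5e-8, maf_min: float = 0.001,
                      maf: pd.Series | None = None) -> pd.DataFrame:
    """Union of univariate and multivariate significant sex-het SNPs.

    ``univariate`` maps trait -> trait-specific sex-het table (already
    filtered); ``meta`` is the full MetaHetRecord table.  The MAF filter is
    re-applied to the meta results using ``maf`` (snp_id -> maf).  Each SNP is
    tagged univariate_only / multivariate_only / both, and carries the
    leading trait and best per-trait P_Q.
    """
    uni_snps: set = set()
    for t, df in univariate.items():
        uni_snps.update(df["snp_id"])
    meta_sig = meta[meta["p_meta"] < p_threshold]
    if maf is not None:
        mvals = meta_sig["snp_id"].map(maf)
        meta_sig = meta_sig[mvals >= maf_min]
    multi_snps = set(meta_sig["snp_id"])

    all_snps = sorted(uni_snps | multi_snps)
    meta_lead = dict(zip(meta["snp_id"], meta["leading_trait"]))
    meta_best = dict(zip(meta["snp_id"], meta["best_p_q"]))
    uni_pq = {t: dict(zip(df["snp_id"], df["p_q"])) for t, df in univariate.items()}
    rows = []
    for snp in all_snps:
        in_uni, in_multi = snp in uni_snps, snp in multi_snps
        prov = "both" if (in_uni and in_multi) else (
            "univariate_only" if in_uni else "multivariate_only")
        lead = meta_lead.get(snp)
        best = meta_best.get(snp, np.inf)
        # univariate tables may sharpen best_p_q for SNPs absent from meta
        for t, pq in uni_pq.items():
            if snp in pq and pq[snp] < best:
                best, lead = pq[snp], t
        rows.append((snp, prov, lead, best))
    out = pd.DataFrame(rows, columns=["snp_id", "provenance", "leading_trait", "best_p_q"])
    return out
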