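"""Reading, validation and harmonization of GWAS summary statistics and annotation tables.

Summary statistics are carried as :class:`pandas.DataFrame` objects with a fixed
canonical column schema (:data:`SUMSTATS_COLUMNS`).  A *paired* table joins the
female and male strata of one trait on a shared effect-allele orientation and is
the input to all heterogeneity statistics.

Auxiliary inputs (gene models, pLI scores, GMT gene sets, BED interval sets,
meQTL and Pr-eQTL maps) are bundled in :class:`AnnotationTables`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a single-stratum summary-statistics table
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: header synonyms seen in common consortium releases, used when no explicit
#: dialect mapping is supplied
DEFAULT_SYNONYMS = {
    "snp_id": ["snp_id", "snp", "rsid", "markername", "variant", "variant_id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "allele1", "ea", "minor_allele"],
    "other_allele": ["other_allele", "a2", "allele2", "oa", "nea", "major_allele"],
    "eaf": ["eaf", "freq", "frq", "af", "effect_allele_frequency", "freq1.hapmap", "maf"],
    "beta": ["beta", "b", "effect", "beta1"],
    "se": ["se", "stderr", "standard_error"],
    "pvalue": ["pvalue", "p", "pval", "p_value", "p.value"],
    "n": ["n", "nsamples", "sample_size", "n_complete_samples"],
}

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _open(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _resolve_dialect(columns, dialect=None):
    """Map canonical field names to actual file columns; hard error if a
    mandatory field cannot be located."""
    mapping = {}
    lower = {c.lower(): c for c in columns}
    for canon in SUMSTATS_COLUMNS:
        if dialect and canon in dialect:
            if dialect[canon] not in columns:
                raise ValueError(f"mapped column {dialect[canon]!r} for {canon!r} not in file")
            mapping[canon] = dialect[canon]
            continue
        for syn in DEFAULT_SYNONYMS[canon]:
            if syn in lower:
                mapping[canon] = lower[syn]
                break
        else:
            raise ValueError(f"mandatory column {canon!r} not found; supply a dialect mapping")
    return mapping


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the table invariants, dropping offending rows.

    Returns the validated table and the number of rows dropped.  Invariants:
    eaf in [0,1]; se > 0; pvalue in (0,1]; alleles differ and are ACGT;
    pos >= 1; no duplicate snp_id (first occurrence kept).
    """
    n0 = len(df)
    df = df.copy()
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df["effect_allele"], df["other_allele"] = ea, oa
    ok = (
        df[["pos", "eaf", "beta", "se", "pvalue", "n"]].notna().all(axis=1)
        & df["eaf"].between(0.0, 1.0)
        & (df["se"] > 0)
        & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & (df["pos"] >= 1)
        & ea.str.fullmatch("[ACGT]+")
        & oa.str.fullmatch("[ACGT]+")
        & (ea != oa)
    )
    df = df[ok.fillna(False)]
    df = df.drop_duplicates(subset="snp_id", keep="first")
    df = df.astype({"pos": np.int64, "n": np.int64})
    dropped = n0 - len(df)
    if dropped:
        logger.warning("validate_sumstats: dropped %d/%d rows failing invariants", dropped, n0)
    return df.reset_index(drop=True), dropped


def read_sumstats(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into the canonical schema.

    ``dialect`` maps canonical names (keys of :data:`DEFAULT_SYNONYMS`) to the
    file's column headers; when omitted, common consortium headers are
    auto-detected.  Rows failing invariants are dropped with a logged count.
    """
    with _open(path) as fh:
        raw = pd.read_csv(fh, sep="\t", dtype=str)
    mapping = _resolve_dialect(list(raw.columns), dialect)
    df = raw[[mapping[c] for c in SUMSTATS_COLUMNS]].copy()
    df.columns = SUMSTATS_COLUMNS
    df, _ = validate_sumstats(df)
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a canonical summary-statistics table as tab-delimited text."""
    df[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def harmonize_pair(female: pd.DataFrame, male: pd.DataFrame) -> pd.DataFrame:
    """Join female and male tables of one trait on a shared allele orientation.

    Strand-ambiguous SNPs (A/T, C/G) are dropped: their orientation cannot be
    resolved from summary data.  Where male alleles are swapped relative to the
    female record, the male beta is negated and eaf replaced by 1-eaf.  SNPs
    whose allele pairs do not match either way are dropped.  ``maf`` is
    computed from the female-stratum eaf; ``n_total`` = n_female + n_male.
    """
    m = female.merge(male, on="snp_id", suffixes=("_f", "_m"))
    if m.empty:
        raise ValueError("harmonize_pair: empty SNP intersection between strata")
    n0 = len(m)

    def ambiguous(ea, oa):
        return pd.Series(list(zip(ea, oa)), index=ea.index).isin(AMBIGUOUS_PAIRS)

    amb = ambiguous(m["effect_allele_f"], m["other_allele_f"]) | ambiguous(
        m["effect_allele_m"], m["other_allele_m"])
    same = (m["effect_allele_f"] == m["effect_allele_m"]) & (
        m["other_allele_f"] == m["other_allele_m"])
    swapped = (m["effect_allele_f"] == m["other_allele_m"]) & (
        m["other_allele_f"] == m["effect_allele_m"])
    keep = ~amb & (same | swapped)
    m = m[keep].copy()
    if m.empty:
        raise ValueError("harmonize_pair: no SNPs with matchable alleles")
    flip = swapped[keep]
    m.loc[flip, "beta_m"] = -m.loc[flip, "beta_m"]
    m.loc[flip, "eaf_m"] = 1.0 - m.loc[flip, "eaf_m"]
    dropped = n0 - len(m)
    if dropped:
        logger.warning("harmonize_pair: dropped %d/%d SNPs (ambiguous or mismatched alleles)",
                       dropped, n0)
    out = pd.DataFrame({
        "snp_id": m["snp_id"],
        "chrom": m["chrom_f"],
        "pos": m["pos_f"],
        "effect_allele": m["effect_allele_f"],
        "other_allele": m["other_allele_f"],
        "eaf_f": m["eaf_f"], "beta_f": m["beta_f"], "se_f": m["se_f"],
        "p_f": m["pvalue_f"], "n_f": m["n_f"],
        "eaf_m": m["eaf_m"], "beta_m": m["beta_m"], "se_m": m["se_m"],
        "p_m": m["pvalue_m"], "n_m": m["n_m"],
    })
    out["maf"] = np.minimum(out["eaf_f"], 1.0 - out["eaf_f"])
    out["n_total"] = out["n_f"] + out["n_m"]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation tables


@dataclass
class AnnotationTables:
    """Container for all non-sumstats inputs consumed by downstream stages."""

    gene_models: pd.DataFrame | None = None   # gene_id, chrom, start, end, strand (1-based inclusive)
    exons: pd.DataFrame | None = None         # gene_id, start, end
    utrs: pd.DataFrame | None = None          # gene_id, start, end
    pli: pd.Series | None = None              # gene_id -> score in [0, 1]
    gene_sets: dict = field(default_factory=dict)   # set name -> list of gene ids
    intervals: dict = field(default_factory=dict)   # annotation name -> BED DataFrame
    meqtl: pd.DataFrame | None = None         # snp_id, cpg, p, tissue
    preqtl: pd.DataFrame | None = None        # snp_id, egene, tissue


def read_gmt(path) -> dict:
    """Read a GMT file: one gene set per line (name, description, genes...)."""
    sets = {}
    with _open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                logger.warning("read_gmt: dropping malformed line %d", i + 1)
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end (+ name)."""
    rows = []
    with _open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split()
            try:
                start, end = int(parts[1]), int(parts[2])
            except (IndexError, ValueError):
                logger.warning("read_bed: dropping malformed line %d", i + 1)
                continue
            if not start < end:
                logger.warning("read_bed: dropping empty interval at line %d", i + 1)
                continue
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def bed_contains(bed: pd.DataFrame, chrom: str, pos: int) -> bool:
    """True iff the 1-based position ``pos`` falls in any interval of ``bed``."""
    sub = bed[bed["chrom"] == chrom]
    return bool(((sub["start"] < pos) & (pos <= sub["end"])).any())


def read_pli(path) -> pd.Series:
    """Read a two-column (gene, pLI) table into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "pli"],
                     comment="#", dtype={"gene": str})
    df["pli"] = pd.to_numeric(df["pli"], errors="coerce")
    bad = df["pli"].isna() | ~df["pli"].between(0, 1)
    if bad.any():
        logger.warning("read_pli: dropping %d malformed rows", int(bad.sum()))
    df = df[~bad]
    return pd.Series(df["pli"].values, index=df["gene"].values, name="pli")


def read_qtl_map(path, item_col: str = "item") -> pd.DataFrame:
    """Read a tab-delimited SNP->item QTL map.

    Expected columns: snp, item (CpG probe or eGene), then optionally p and
    tissue.  Returns columns snp_id, <item_col>, p (NaN when absent), tissue.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("QTL map needs at least two columns (snp, item)")
    out = pd.DataFrame({"snp_id": df[cols[0]], item_col: df[cols[1]]})
    out["p"] = pd.to_numeric(df[cols[2]], errors="coerce") if len(cols) > 2 else np.nan
    out["tissue"] = df[cols[3]] if len(cols) > 3 else "na"
    bad = out["snp_id"].isna() | out[item_col].isna() | (out[item_col] == "")
    if bad.any():
        logger.warning("read_qtl_map: dropping %d malformed rows", int(bad.sum()))
    return out[~bad].reset_index(drop=True)
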