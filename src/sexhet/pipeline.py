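"""End-to-end orchestration: discover -> clump -> match -> enrich -> annotate -> ORA.

`run_pipeline` executes the full analysis from a single config mapping (or
YAML path), on synthetic inputs generated in-process, and writes stage
outputs plus a reproducibility manifest (config hash, seeds, per-output
checksums, stage timings).  Deterministic stages are pure functions of
(config, inputs, seed): re-running with the same config yields identical
output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichment as enr
from . import gene_annotation as ga
from . import het_stats, matched_null, multitrait_meta, ora
from .ld_clump import clump
from .sumstats_io import harmonize_pair
from .synthetic_data import SimConfig, simulate_annotations, simulate_disease, simulate_sumstats

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "sexhet_out",
    "simulate": {"n_snps": 20_000, "n_traits": 3},
    "discovery": {"p_threshold": 5e-8, "maf_min": 0.001},
    "meta": {"use_overlap_correction": True, "null_band": 1.0},
    "clump": {"r2_threshold": 0.2},
    "match": {"n_sets": 100, "rank_window": 75},
    "enrich": {"alpha": 0.05},
    "annotate": {"cutoff_bp": 25_000},
    "ora": {},
}


def load_config(path_or_mapping) -> dict:
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_mapping or {})
    cfg = {}
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            cfg[key] = {**default, **(user.get(key) or {})}
        else:
            cfg[key] = user.get(key, default)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def build_catalog(tables: dict, ld, p_threshold: float = 5e-8,
                  maf_min: float = 0.001, use_overlap_correction: bool = True,
                  null_band: float = 1.0, r2_threshold: float = 0.2):
    """Core discovery: per-trait heterogeneity, cross-trait meta, clumping.

    ``tables[trait] = (female_df, male_df)``.  Returns (catalog, paired dict,
    het-table dict, meta table).
    """
    paired, hets, uni = {}, {}, {}
    for trait, (female, male) in tables.items():
        p = harmonize_pair(female, male)
        paired[trait] = p
        het = het_stats.het_table(p)
        hets[trait] = het
        keep = (het["p_q"] < p_threshold) & (het["maf"] >= maf_min)
        uni[trait] = het[keep]

    traits = list(tables)
    idx = hets[traits[0]]["snp_id"]
    beta_w = pd.DataFrame(index=idx)
    se_w = pd.DataFrame(index=idx)
    pq_w = pd.DataFrame(index=idx)
    z_w = pd.DataFrame(index=idx)
    for trait in traits:
        het = hets[trait].set_index("snp_id")
        signed = multitrait_meta.signed_input(het["beta_het"], het["beta_f"], het["beta_m"])
        beta_w[trait] = pd.Series(signed, index=het.index)
        se_w[trait] = het["se_het"]
        pq_w[trait] = het["p_q"]
        z_w[trait] = beta_w[trait] / se_w[trait]
    corr = None
    if use_overlap_correction and len(traits) >= 2:
        corr = multitrait_meta.estimate_overlap_corr(z_w, null_band=null_band)
    meta = multitrait_meta.meta_analyse(beta_w.dropna(how="all"),
                                        se_w.dropna(how="all"), pq_w, corr=corr)

    ref = paired[traits[0]].set_index("snp_id")
    candidates = multitrait_meta.combine_uni_multi(
        uni, meta, p_threshold=p_threshold, maf_min=maf_min, maf=ref["maf"])
    candidates["chrom"] = candidates["snp_id"].map(ref["chrom"])
    candidates["pos"] = candidates["snp_id"].map(ref["pos"])
    candidates["maf"] = candidates["snp_id"].map(ref["maf"])
    if candidates.empty:
        return candidates, paired, hets, meta
    catalog = clump(candidates, ld, r2_threshold=r2_threshold)

    # direction/mechanism from the leading trait's stratum statistics
    dirs, mechs = [], []
    for snp, lead in zip(catalog["snp_id"], catalog["leading_trait"]):
        het = hets[lead].set_index("snp_id") if lead in hets else None
        if het is None or snp not in het.index:
            dirs.append(None)
            mechs.append(None)
            continue
        row = het.loc[snp]
        dirs.append(het_stats.classify_direction(row["beta_f"], row["beta_m"]))
        mechs.append(het_stats.classify_mechanism(row["p_f"], row["p_m"],
                                                  row["beta_f"], row["beta_m"]))
    catalog["direction"] = dirs
    catalog["mechanism"] = mechs
    return catalog, paired, hets, meta


def run_pipeline(config, outdir=None) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    cfg = load_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()

    def stage_done(name, *paths):
        manifest["stages"][name] = round(time.time() - t0, 3)
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    try:
        sim = SimConfig(seed=cfg["seed"], **cfg["simulate"])
        tables, truth = simulate_sumstats(sim)
        ann, ld = simulate_annotations(sim, truth)
        disease = simulate_disease(sim, truth)
        stage_done("simulate")

        d = cfg["discovery"]
        catalog, paired, hets, meta = build_catalog(
            tables, ld, p_threshold=d["p_threshold"], maf_min=d["maf_min"],
            use_overlap_correction=cfg["meta"]["use_overlap_correction"],
            null_band=cfg["meta"]["null_band"],
            r2_threshold=cfg["clump"]["r2_threshold"])
        cat_path = _write(catalog, out / "catalog.tsv")
        stage_done("discover", cat_path)
        if catalog.empty:
            manifest["failed_stage"] = "discover (empty catalog)"
            return _finish(manifest, out)

        m = cfg["match"]
        indexes = {
            trait: matched_null.build_index(paired[trait], catalog["snp_id"], ld)
            for trait in set(catalog["leading_trait"])
        }
        sampler = matched_null.MatchedNullSampler(indexes, catalog,
                                                  rank_window=m["rank_window"])
        children = np.random.SeedSequence(cfg["seed"]).spawn(m["n_sets"])
        null_sets = [sampler.sample(c) for c in children]
        pool0 = paired[next(iter(paired))]
        diag = matched_null.matching_diagnostics(catalog["maf"], null_sets, pool0["maf"])
        diag_path = _write(diag, out / "matching_diagnostics.tsv")
        stage_done("match", diag_path)

        alpha = cfg["enrich"]["alpha"]
        results = [enr.signal_enrichment_empirical(
            catalog["snp_id"], disease, null_sets, alpha=alpha, name="disease")]
        meqtl = ann.meqtl[ann.meqtl["p"] < 1e-14]
        meqtl_items = meqtl.groupby("snp_id")["cpg"].agg(set).to_dict()
        results.append(enr.snpset_overlap_empirical(
            catalog["snp_id"], set(meqtl["snp_id"]), null_sets,
            per_snp_items=meqtl_items, name="meqtl"))
        pre_items = ann.preqtl.groupby("snp_id")["egene"].agg(set).to_dict()
        results.append(enr.snpset_overlap_empirical(
            catalog["snp_id"], set(ann.preqtl["snp_id"]), null_sets,
            per_snp_items=pre_items, name="preqtl_all"))
        brain = ann.preqtl[ann.preqtl["tissue"].str.startswith("brain")]
        brain_items = brain.groupby("snp_id")["egene"].agg(set).to_dict()
        results.append(enr.snpset_overlap_empirical(
            catalog["snp_id"], set(brain["snp_id"]), null_sets,
            per_snp_items=brain_items, name="preqtl_brain"))
        pos = truth.set_index("snp_id")[["chrom", "pos"]]
        null_pos = [pos.loc[s["snp_id"]].reset_index() for s in null_sets]
        for name, bed in ann.intervals.items():
            results.append(enr.interval_overlap_empirical(
                catalog, bed, null_pos, name=name))
        enr_path = _write(enr.results_table(results), out / "enrichment.tsv")
        stage_done("enrich", enr_path)

        cut = cfg["annotate"]["cutoff_bp"]
        assign = ga.annotate_snps(catalog, ann.gene_models, ann.exons, ann.utrs,
                                  cutoff_bp=cut)
        genes = ga.gene_list(assign)
        ref_props = {
            "pli>0.9": float((ann.pli > 0.9).mean()),
            "pli<0.1": float((ann.pli < 0.1).mean()),
        }
        constraint = ga.constraint_enrichment(genes, ann.pli, ref_props)
        a_path = _write(assign, out / "gene_assignments.tsv")
        c_path = _write(constraint, out / "constraint.tsv")
        stage_done("annotate", a_path, c_path)

        universe = ann.gene_models["gene_id"].tolist()
        observed = ora.ora_collection(genes, ann.gene_sets, universe)
        perm_lists = []
        for s in null_sets:
            snps = pos.loc[s["snp_id"]].reset_index()
            perm_lists.append(ga.gene_list(
                ga.annotate_snps(snps, ann.gene_models, ann.exons, ann.utrs,
                                 cutoff_bp=cut)))
        ora_table = ora.ora_empirical(observed, perm_lists, ann.gene_sets, universe)
        o_path = _write(ora_table, out / "ora.tsv")
        stage_done("ora", o_path)
    except Exception as exc:  # partial manifest with failure marker
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        _finish(manifest, out)
        raise
    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
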