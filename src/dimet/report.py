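"""End-to-end pipeline driver: stages, output TSVs, manifest, run report.

``run_pipeline`` executes simulate/load -> preprocess -> WT sex scan ->
KO dimorphism tests -> cluster enrichment -> phenotype associations, writes
every result as TSV, and renders a markdown report whose tables mirror the
standard presentation of such screens: sex-effect direction counts, the
per-category decomposition of significant KO effects globally and per
line, and the correlation dimorphism summary.  A manifest records the
configuration echo and SHA-256 hashes of all inputs and outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import replace

import pandas as pd

from . import associations, dimorphism, enrichment, io, preprocess, simulate, wt_sex
from .config import RunConfig
from .tables import ValidationError

log = logging.getLogger("dimet")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig, outdir: str):
    if cfg.simulate:
        sim_cfg = simulate.study_preset(seed=cfg.seed, **cfg.sim_overrides)
        table, meta, annot, pheno, truth = simulate.simulate_cohort(sim_cfg)
        io.write_abundance(table, os.path.join(outdir, "abundance.tsv"))
        io.write_sample_meta(meta, os.path.join(outdir, "samples.tsv"))
        io.write_annotation(annot, os.path.join(outdir, "features.tsv"))
        io.write_phenotypes(pheno, os.path.join(outdir, "phenotypes.tsv"))
        io.write_table(truth.frame, os.path.join(outdir, "truth.tsv"))
        inputs = {}
    else:
        table, meta, annot = io.read_abundance(
            cfg.abundance_path, cfg.meta_path, cfg.annotation_path)
        pheno = (io.read_phenotypes(cfg.phenotype_path)
                 if cfg.phenotype_path else None)
        truth = None
        inputs = {p: _sha256(p) for p in (
            cfg.abundance_path, cfg.meta_path, cfg.annotation_path,
            cfg.phenotype_path) if p}
    return table, meta, annot, pheno, truth, inputs


def run_pipeline(cfg: RunConfig, outdir: str) -> dict:
    """Run every stage and write the report; returns the summary dict."""
    os.makedirs(outdir, exist_ok=True)
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    table, meta, annot, pheno, truth, input_hashes = _load_inputs(cfg, outdir)

    log.info("preprocess: %d features in", len(table.feature_ids))
    prep = preprocess.preprocess_cohort(
        table, meta, annot, pheno,
        rsd_max=cfg.rsd_max, missing_max=cfg.missing_max,
        prevalence_min=cfg.prevalence_min,
        normalize_platforms=cfg.normalize_platforms)
    clean = prep["table"]
    io.write_table(prep["removal_log"], os.path.join(outdir, "removed_features.tsv"))
    log.info("preprocess: %d features retained", len(clean.feature_ids))

    sex_res = wt_sex.sex_scan(clean, meta, adjust_weight=cfg.adjust_weight,
                              variance_mode=cfg.variance_mode,
                              alpha=cfg.alpha, use_fdr=cfg.fdr)
    sex_sum = wt_sex.summarize_sex_effects(sex_res, alpha=cfg.alpha, use_fdr=cfg.fdr)
    io.write_table(sex_res, os.path.join(outdir, "wt_sex_effects.tsv"))

    clusters = annot.clusters(clean.feature_ids) if annot is not None else None
    sex_enrich = None
    if clusters is not None:
        sp = sex_res.set_index("feature_id")
        sex_enrich = enrichment.enrich_clusters(
            sp["p_value"], sp["estimate"].apply(lambda v: 1 if v > 0 else -1),
            clusters, alpha=cfg.alpha, min_size=cfg.min_cluster_size)
        io.write_table(sex_enrich, os.path.join(outdir, "wt_sex_enrichment.tsv"),
                       sort_by=["cluster"])

    ko_res = dimorphism.test_all_lines(
        clean, meta, alpha=cfg.alpha, welch=cfg.welch,
        gate_on_genotype=cfg.gate_on_genotype, fdr=cfg.fdr)
    ko_sum = dimorphism.summarize_ko(ko_res, alpha=cfg.alpha)
    io.write_table(ko_res, os.path.join(outdir, "ko_dimorphism.tsv"))
    io.write_table(ko_sum["per_line"], os.path.join(outdir, "ko_summary_per_line.tsv"),
                   sort_by=["ko_line"])

    corr_sum = heat = None
    if prep["pheno"] is not None and len(prep["pheno"].phenotype_ids):
        corr = associations.spearman_by_sex(
            clean, prep["pheno"], meta, alpha=cfg.alpha, min_n=cfg.min_corr_n)
        corr_sum = associations.categorize_summary(corr)
        io.write_table(corr, os.path.join(outdir, "phenotype_correlations.tsv"))
        if clusters is not None and len(corr):
            heat = associations.cluster_phenotype_matrix(
                corr, clusters, alpha=cfg.alpha, min_size=cfg.min_cluster_size)
            io.write_table(heat, os.path.join(outdir, "phenotype_cluster_heatmap.tsv"),
                           sort_by=["phenotype_id", "cluster", "sex"])

    summary = {
        "attrition": prep["attrition"],
        "phenotypes_dropped": prep["pheno_dropped"],
        "wt_sex": sex_sum,
        "ko": ko_sum["global"],
        "correlations": corr_sum,
        "n_enriched_sex_clusters": (
            int(sex_enrich["significant"].sum()) if sex_enrich is not None else None),
    }
    _write_report(outdir, cfg, summary, ko_sum["per_line"])

    manifest = {
        "config": cfg.to_yaml(),
        "inputs": input_hashes,
        "outputs": {},
    }
    for name in sorted(os.listdir(outdir)):
        p = os.path.join(outdir, name)
        if os.path.isfile(p) and name != "manifest.json":
            manifest["outputs"][name] = _sha256(p)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _md_table(d: dict) -> str:
    lines = ["| quantity | value |", "| --- | --- |"]
    for k, v in d.items():
        if isinstance(v, float):
            v = f"{v:.4g}"
        lines.append(f"| {k} | {v} |")
    return "\n".join(lines)


def _write_report(outdir: str, cfg: RunConfig, summary: dict,
                  per_line: pd.DataFrame) -> None:
    parts = ["# Dimorphism pipeline report", ""]
    parts += ["## Feature attrition", "", _md_table(summary["attrition"]), ""]
    parts += ["## Wildtype sex effects", "", _md_table(summary["wt_sex"]), ""]
    parts += ["## Knockout effects (global)", "", _md_table(summary["ko"]), ""]
    parts += ["## Knockout effects per line", "",
              per_line.to_markdown(index=False) if len(per_line) else "none", ""]
    if summary["correlations"] is not None:
        parts += ["## Metabolite-phenotype correlations", "",
                  _md_table(summary["correlations"]), ""]
    if summary["n_enriched_sex_clusters"] is not None:
        parts += ["## Enriched chemical clusters (WT sex contrast)", "",
                  f"significant clusters: {summary['n_enriched_sex_clusters']}", ""]
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(parts))
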