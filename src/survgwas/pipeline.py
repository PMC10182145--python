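"""End-to-end pipeline: simulate/QC/PCA/clinical/scan/enrich/risk + run report.

Driven by a single YAML config; every stage writes its documented artifact
into the output directory and the run report lists each output file with a
content hash, the QC removal counts, the genomic inflation factor, the top
suggestive loci, the enrichment empirical P per threshold, and the
risk-model metrics.  Stages are deterministic given the seeds in the
config, so rerunning a config reproduces the manifest hashes exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import vcfio
from .containers import ValidationError, align_subjects
from .enrich import DEFAULT_THRESHOLDS, GeneRegionSet, PermutationEnrichment, map_snps_to_regions
from .pca import genotype_pca
from .qc import variant_qc
from .riskmodel import CoxRiskScore, split_train_test
from .scan import SUGGESTIVE_P, ScanConfig, genomic_inflation, gwas_scan, qq_manhattan_tables
from .simulate import SimConfig, simulate_dataset, with_encoded


DEFAULT_CONFIG: dict = {
    "out_dir": "survgwas_run",
    "paths": {"vcf": None, "phenotypes": None, "genes": None, "gene_set": None},
    "simulate": {"enabled": True},  # extra keys are SimConfig fields
    "qc": {"call_rate_min": 0.95, "maf_min": 0.01, "hwe_p_min": 1e-12, "info_min": None},
    "pca": {"n_components": 2},
    "scan": {"covariates": ["age_ge50", "t34", "conc_cis_high", "PC1", "PC2"],
             "ties": "efron"},
    "enrich": {"flank": 50000, "thresholds": list(DEFAULT_THRESHOLDS),
               "n_permutations": 1000, "seed": 0},
    "risk": {"n_top_snps": 8, "clinical_terms": ["age_ge50", "t34", "conc_cis_high"],
             "snp_ids": None, "horizon": 60.0, "split_seed": 0, "split_ratio": 0.5},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages in order; returns the run report dict."""
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "stages": {}, "outputs": {}}

    def emit(name: str, path: Path) -> None:
        report["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # ---- load or simulate --------------------------------------------------
    sim_cfg = cfg.get("simulate", {})
    if sim_cfg.get("enabled", False):
        fields = {f.name for f in dataclasses.fields(SimConfig)}
        kwargs = {k: v for k, v in sim_cfg.items() if k in fields}
        if "maf_range" in kwargs:
            kwargs["maf_range"] = tuple(kwargs["maf_range"])
        sim = SimConfig(**kwargs)
        g, cohort, genes, gene_set = simulate_dataset(sim)
        paths = vcfio.write_dataset(g, cohort, genes, gene_set, out_dir / "data")
        for k, p in paths.items():
            emit(f"data/{k}", p)
        report["stages"]["simulate"] = {"n_subjects": g.n_subjects, "n_variants": g.n_variants,
                                        "n_events": int(cohort["event"].sum())}
    else:
        p = cfg["paths"]
        for key in ("vcf", "phenotypes", "genes", "gene_set"):
            if not p.get(key) or not Path(p[key]).exists():
                raise ValidationError(f"input path {key!r} missing or nonexistent: {p.get(key)}")
        g = vcfio.read_vcf(p["vcf"])
        cohort = vcfio.read_phenotypes(p["phenotypes"])
        genes = vcfio.read_bed(p["genes"])
        gene_set = vcfio.read_gene_set(p["gene_set"])
        g, cohort = align_subjects(g, cohort)

    # ---- QC ----------------------------------------------------------------
    qc_cfg = cfg["qc"]
    g_qc, qc_report = variant_qc(g, call_rate_min=qc_cfg["call_rate_min"],
                                 maf_min=qc_cfg["maf_min"], hwe_p_min=qc_cfg["hwe_p_min"],
                                 info_min=qc_cfg["info_min"])
    qc_path = out_dir / "qc_report.tsv"
    qc_report.metrics.to_csv(qc_path, sep="\t", index=False)
    emit("qc_report", qc_path)
    report["stages"]["qc"] = {"n_input": qc_report.n_input,
                              "n_retained": qc_report.n_retained,
                              "removed_by_filter": qc_report.removed_by_filter}

    # ---- PCA ---------------------------------------------------------------
    pcs, evr = genotype_pca(g_qc, k=cfg["pca"]["n_components"])
    pcs_path = out_dir / "pcs.tsv"
    pcs.to_csv(pcs_path, sep="\t")
    emit("pcs", pcs_path)
    report["stages"]["pca"] = {"explained_variance_ratio": [float(x) for x in evr]}

    # ---- covariate encoding + scan ----------------------------------------
    cohort_enc = with_encoded(cohort, pcs)
    scan_cfg = ScanConfig(covariates=tuple(cfg["scan"]["covariates"]),
                          ties=cfg["scan"]["ties"])
    results = gwas_scan(g_qc, cohort_enc, pcs=None, cfg=scan_cfg)
    scan_path = out_dir / "scan_results.tsv"
    results.to_csv(scan_path, sep="\t", index=False)
    emit("scan_results", scan_path)
    lam = genomic_inflation(results.loc[results["converged"], "p"])
    qq, manhattan = qq_manhattan_tables(results)
    qq.to_csv(out_dir / "qq.tsv", sep="\t", index=False)
    manhattan.to_csv(out_dir / "manhattan.tsv", sep="\t", index=False)
    emit("qq", out_dir / "qq.tsv")
    emit("manhattan", out_dir / "manhattan.tsv")
    top = results.loc[results["converged"] & (results["p"] < SUGGESTIVE_P)]
    report["stages"]["scan"] = {
        "lambda_gc": lam,
        "n_suggestive": int(len(top)),
        "top_loci": top.nsmallest(10, "p")[["variant_id", "chrom", "pos", "hr", "p"]]
                       .to_dict("records"),
    }

    # ---- enrichment --------------------------------------------------------
    en_cfg = cfg["enrich"]
    regions = GeneRegionSet(genes, flank=en_cfg["flank"]).subset(gene_set)
    membership, _ = map_snps_to_regions(g_qc.variants, regions)
    if membership.sum() == 0:
        report["stages"]["enrich"] = {"skipped": "no member variants in the gene set"}
    else:
        enr = PermutationEnrichment(thresholds=tuple(en_cfg["thresholds"]),
                                    n_permutations=en_cfg["n_permutations"],
                                    covariates=tuple(cfg["scan"]["covariates"]),
                                    seed=en_cfg["seed"])
        enr.fit(g_qc, cohort_enc, membership)
        enr_path = out_dir / "enrichment.tsv"
        enr.result_frame().to_csv(enr_path, sep="\t", index=False)
        emit("enrichment", enr_path)
        report["stages"]["enrich"] = {
            "n_member_snps": int(membership.sum()),
            "empirical_p": {f"{t:g}": float(p)
                            for t, p in zip(enr.thresholds_, enr.empirical_p_)},
        }

    # ---- risk model --------------------------------------------------------
    rk = cfg["risk"]
    snp_ids = rk.get("snp_ids")
    if not snp_ids:  # default: top-N converged scan hits
        snp_ids = list(results.loc[results["converged"]].nsmallest(
            rk["n_top_snps"], "p")["variant_id"])
    train, test = split_train_test(cohort_enc, ratio=rk["split_ratio"], seed=rk["split_seed"])
    model = CoxRiskScore(snp_ids=snp_ids, clinical_terms=tuple(rk["clinical_terms"]),
                         horizon=rk["horizon"])
    model.fit(train, g_qc)
    metrics = {name: model.evaluate(part, g_qc)
               for name, part in (("train", train), ("test", test), ("all", cohort_enc))}
    model_path = out_dir / "risk_model.json"
    model_path.write_text(json.dumps({
        "terms": model.terms_, "coefficients": [float(b) for b in model.coef_],
        "cutoff": model.cutoff_, "horizon": model.horizon,
        "metrics": metrics,
    }, indent=2))
    emit("risk_model", model_path)
    report["stages"]["risk"] = {"terms": model.terms_, "cutoff": model.cutoff_,
                                "n_train": len(train), "n_test": len(test),
                                "metrics": metrics}

    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    report["outputs"]["run_report"] = {"path": str(report_path)}
    return report
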