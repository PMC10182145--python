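"""Reading and writing the pipeline's on-disk formats.

VCF v4.2 for genotypes (GT for hard calls, DS for dosages, an INFO=
record-level tag for imputation quality), TSV for the phenotype/cohort
table, BED (0-based half-open) for gene intervals, and a newline-delimited
text file for the curated gene set.  Reading VCF goes through cyvcf2; the
writer is a deterministic text emitter so a written dataset round-trips
bit-identically given the same inputs.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ValidationError, check_cohort

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=survgwas
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Parse a biallelic VCF v4.2 into a GenotypeMatrix.

    DS (dosage) is preferred when present; otherwise GT hard calls are used
    with ``./.`` mapped to missing.  Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.array(vcf.samples, dtype=object)
    rows, dosages, infos = [], [], []
    has_info = False
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"multiallelic record not supported: {rec.CHROM}:{rec.POS} (record {i + 1})")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
            col = np.where(col < 0, np.nan, col)
        else:
            col = np.empty(len(subjects))
            for s, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1]
                col[s] = np.nan if (a < 0 or b < 0) else float(a + b)
        info = rec.INFO.get("INFO")
        has_info = has_info or info is not None
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        infos.append(np.nan if info is None else float(info))
        dosages.append(col)
    if not rows:
        raise ValidationError(f"no variant records in {path}")
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    if has_info:
        variants["info_score"] = infos
    return GenotypeMatrix(subjects, variants, np.column_stack(dosages))


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write VCF v4.2: GT for integral dosages, DS otherwise; ``./.`` for missing."""
    hard = np.all(np.isnan(g.dosage) | (np.rint(g.dosage) == g.dosage))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.subject_ids)) + "\n")
        has_info = "info_score" in g.variants.columns
        for j, var in g.variants.iterrows():
            info_field = "."
            if has_info and np.isfinite(var["info_score"]):
                info_field = f"INFO={var['info_score']:.6g}"
            col = g.dosage[:, j]
            if hard:
                gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                calls = ["./." if np.isnan(x) else gt[float(np.rint(x))] for x in col]
                fmt = "GT"
            else:
                calls = ["." if np.isnan(x) else f"{x:.6g}" for x in col]
                fmt = "DS"
            fh.write("\t".join([
                str(var["chrom"]), str(int(var["pos"])), str(var["variant_id"]),
                str(var["ref"]), str(var["alt"]), ".", "PASS", info_field, fmt,
            ]) + "\t" + "\t".join(calls) + "\n")


def write_phenotypes(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | os.PathLike, require_outcome: bool = True) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", na_values=["NA"])
    cohort["subject_id"] = cohort["subject_id"].astype(str)
    return check_cohort(cohort, require_outcome=require_outcome)


def write_bed(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """BED4: chrom, start (0-based), end (half-open), name."""
    genes[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "name"],
                        dtype={"chrom": str, "start": int, "end": int, "name": str})
    if (genes["end"] <= genes["start"]).any():
        raise ValidationError("BED intervals must satisfy start < end")
    return genes


def write_gene_set(names: list[str], path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in names))


def read_gene_set(path: str | os.PathLike) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_dataset(g: GenotypeMatrix, cohort: pd.DataFrame, genes: pd.DataFrame,
                  gene_set: list[str], out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the full dataset (VCF + phenotype TSV + BED + gene-set text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "genes": out / "genes.bed",
        "gene_set": out / "gene_set.txt",
    }
    write_vcf(g, paths["vcf"])
    write_phenotypes(cohort, paths["phenotypes"])
    write_bed(genes, paths["genes"])
    write_gene_set(gene_set, paths["gene_set"])
    return paths


def read_dataset(in_dir: str | os.PathLike):
    """Round-trip counterpart of :func:`write_dataset`."""
    d = Path(in_dir)
    return (read_vcf(d / "genotypes.vcf"),
            read_phenotypes(d / "phenotypes.tsv"),
            read_bed(d / "genes.bed"),
            read_gene_set(d / "gene_set.txt"))
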