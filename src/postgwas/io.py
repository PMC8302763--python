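"""File dialects: summary-statistic TSV, VCF, BED, annotation, weights.

All tabular artifacts are tab-separated.  Positions are 1-based inclusive
everywhere except BED, which is converted to/from 0-based half-open at the
boundary.  Genotypes round-trip through VCF with GT fields (one file per
study); dosage matrices and phenotype/covariate tables have plain TSV
forms for inspection.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CohortMatrix

__all__ = [
    "SUMMARY_COLUMNS",
    "read_summary",
    "write_summary",
    "write_vcf",
    "read_vcf_dosage",
    "read_bed",
    "write_bed",
    "read_annotation",
    "read_weights",
    "write_dosage_tsv",
    "write_phenotype_tsv",
    "load_table1_loci",
    "load_expression_cutoffs",
]

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "FREQ1", "BETA", "SE", "P", "N", "STUDY"]


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary table {path} missing columns: {sorted(missing)}")
    return df


def write_summary(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_vcf(matrix: CohortMatrix, path: str | Path) -> None:
    """Write a cohort's genotypes as a minimal GT-only VCF."""
    samples = list(matrix.covariates.index.astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=postgwas study={matrix.study_id}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(matrix.variants.itertuples(index=False)):
            col = matrix.dosage[:, j]
            gts = [
                "./." if np.isnan(d) else gt_codes[int(d)] for d in col
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.a2}\t{v.a1}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf_dosage(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read GT fields into an effect-allele (ALT) dosage matrix.

    Returns (dosage samples x variants with NaN for missing, variant
    metadata frame, sample names).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        gts = rec.gt_types  # 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        d = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        cols.append(d)
        rows.append((rec.ID, rec.CHROM, rec.POS, rec.ALT[0] if rec.ALT else ".", rec.REF))
    vcf.close()
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2"])
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return dosage, variants, samples


def read_bed(path: str | Path, names: tuple[str, ...] = ("chrom", "start", "end")) -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV with 1-based inclusive spans, or GFF3 gene rows."""
    p = Path(path)
    if p.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(p) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name", attrs.get("ID", "."))
                rows.append((name, f[0], int(f[3]), int(f[4]), f[6]))
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    need = {"gene", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation {path} missing columns: {sorted(need - set(df.columns))}")
    return df


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str})
    need = {"SNP", "A1", "BETA"}
    if not need <= set(df.columns):
        raise ValueError(f"weights {path} missing columns: {sorted(need - set(df.columns))}")
    return df


def write_dosage_tsv(matrix: CohortMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.dosage,
        index=matrix.covariates.index,
        columns=matrix.variants["id"],
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def write_phenotype_tsv(matrix: CohortMatrix, path: str | Path) -> None:
    df = matrix.covariates.copy()
    df.insert(0, "phenotype", matrix.phenotype)
    df.to_csv(path, sep="\t", index_label="sample")


def load_table1_loci() -> pd.DataFrame:
    """The packaged 22-locus susceptibility table (rsID, alleles, OR, P)."""
    with resources.files("postgwas.data").joinpath("table1_loci.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_expression_cutoffs() -> tuple[float, float]:
    """Published fetal germ-cell expression tertile cutoffs (replication mode)."""
    with resources.files("postgwas.data").joinpath(
        "fetal_expression_cutoffs.json"
    ).open() as fh:
        d = json.load(fh)
    return float(d["low_max"]), float(d["medium_max"])
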