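"""Readers and writers for the pipeline's interchange formats.

Matrices (methylation, expression) travel as TSV with the feature id in
the first column and sample ids in the header; genotypes as a minimal
VCF 4.2 (GT field only) or an additive-dosage TSV; coordinates as
BED-like TSV (0-based half-open on disk, 1-based inclusive in memory);
the simulation truth block as JSON. Missing values are encoded "NA".
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_cohort",
    "content_hash",
]

NA = "NA"


def write_matrix_tsv(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    """Write a feature x sample matrix as TSV (first column = feature id)."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index_label="id")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix; '#' header lines are skipped.

    Duplicate feature or sample ids are a hard error (they would
    silently misalign joins downstream).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=[NA])
    df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    return df


def write_table_tsv(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    """Write a per-sample (or per-feature) table with its index column."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index_label=df.index.name or "id")


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=[NA])


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: pd.DataFrame, positions: pd.DataFrame, path) -> None:
    """Minimal VCF 4.2 with GT-only genotype fields.

    ``genotypes`` is SNP x sample additive dosage (NaN = missing);
    ``positions`` gives ``chrom`` and 1-based ``pos`` per variant id.
    Alleles are written as placeholder A (ref) / G (alt).
    """
    path = Path(path)
    samples = list(genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(positions["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        order = positions.sort_values(["chrom", "pos"]).index
        for vid in order:
            if vid not in genotypes.index:
                continue
            row = genotypes.loc[vid]
            gts = "\t".join(
                "./." if not np.isfinite(v) else _GT_CODE[int(v)] for v in row
            )
            fh.write(
                f"{positions.at[vid, 'chrom']}\t{int(positions.at[vid, 'pos'])}\t"
                f"{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF into (additive-dosage DataFrame, positions DataFrame).

    Parsing is delegated to cyvcf2; dosages count alternate alleles per
    GT field, with any missing allele giving NaN.
    """
    from cyvcf2 import VCF

    reader = VCF(str(path))
    samples = list(reader.samples)
    ids, chroms, positions, rows = [], [], [], []
    for var in reader:
        gts = []
        for g in var.genotypes:
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                gts.append(np.nan)
            else:
                gts.append(float(sum(alleles)))
        ids.append(var.ID)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(gts)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids in VCF")
    geno = pd.DataFrame(rows, index=ids, columns=samples)
    pos = pd.DataFrame({"chrom": chroms, "pos": positions}, index=ids)
    return geno, pos


def write_bed(positions: pd.DataFrame, path) -> None:
    """BED-like TSV (chrom, start, end, id); converts 1-based inclusive
    in-memory positions to 0-based half-open on disk."""
    with open(path, "w") as fh:
        for fid, row in positions.iterrows():
            start = int(row["pos"]) - 1
            fh.write(f"{row['chrom']}\t{start}\t{start + 1}\t{fid}\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED-like file back to 1-based inclusive positions."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "id"],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "pos": df["start"].to_numpy() + 1},
        index=df["id"],
    )
    out.index.name = None
    return out


def write_cohort(cohort, outdir, provenance: str | None = None) -> None:
    """Write all matrices, annotations and the truth block of a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(cohort.methylation, outdir / "methylation.tsv", provenance)
    write_matrix_tsv(cohort.expression, outdir / "expression.tsv", provenance)
    write_matrix_tsv(cohort.genotypes, outdir / "dosages.tsv", provenance)
    write_vcf(cohort.genotypes, cohort.snp_positions, outdir / "genotypes.vcf")
    write_table_tsv(cohort.covariates, outdir / "covariates.tsv", provenance)
    write_table_tsv(cohort.phenotypes, outdir / "phenotypes.tsv", provenance)
    write_bed(cohort.cpg_positions, outdir / "cpgs.bed")
    write_bed(cohort.snp_positions, outdir / "snps.bed")
    write_bed(cohort.gene_positions, outdir / "genes.bed")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(_jsonable(cohort.truth), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def content_hash(path) -> str:
    """SHA-256 of a text file ignoring '#' provenance lines (so that
    timestamps in headers do not affect reproducibility checks)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for line in fh:
            if line.startswith(b"#"):
                continue
            h.update(line)
    return h.hexdigest()
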