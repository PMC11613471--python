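"""Readers and writers for the pipeline's plain-text formats.

Genotypes: dosage TSV (variants x samples; columns variant_id, chrom, pos,
ref, alt, then one column per sample) or VCF v4.2 with GT fields.
Expression: counts TSV (genes x samples) plus a gene-annotation TSV
(gene_id, chrom, tss, strand) and an optional covariate TSV.  GWAS
summaries and gene sets (GMT) follow the field's usual column layouts.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionSet, GenotypeMatrix, GwasSummary, VARIANT_COLUMNS

FLOAT_FORMAT = "%.10g"


# -- genotypes --------------------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    meta = genotypes.variants[VARIANT_COLUMNS].reset_index(drop=True)
    dos = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.samples
    ).reset_index(drop=True)
    pd.concat([meta, dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%g"
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta = df[VARIANT_COLUMNS]
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, samples, meta)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT calls from rounded dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    hc = genotypes.hard_calls()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.samples) + "\n")
        for j, row in genotypes.variants.iterrows():
            calls = [
                "./." if np.isnan(hc[i, j]) else gt_map[int(hc[i, j])]
                for i in range(genotypes.n_samples)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (uncompressed or bgzipped) into a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    meta = []
    for v in vcf:
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # unknown
        rows.append(gt)
        meta.append(
            {
                "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
            }
        )
    dosages = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, pd.DataFrame(meta))


# -- expression -------------------------------------------------------------

def write_counts_tsv(es: ExpressionSet, path) -> None:
    out = es.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path, condition: str, gene_annotation: pd.DataFrame,
                    sample_covariates: pd.DataFrame | None = None) -> ExpressionSet:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionSet(
        counts=counts,
        condition=condition,
        gene_annotation=gene_annotation,
        sample_covariates=sample_covariates
        if sample_covariates is not None
        else pd.DataFrame(index=counts.columns),
    )


def write_gene_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t")


def read_gene_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# -- GWAS -------------------------------------------------------------------

def write_gwas_tsv(gwas: GwasSummary, path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gwas_tsv(path, trait: str, trait_type: str = "quant") -> GwasSummary:
    table = pd.read_csv(path, sep="\t")
    return GwasSummary(table=table, trait=trait, trait_type=trait_type)


# -- gene sets --------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, na_rep="NA")
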