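"""Assemble the trait-association table and compare eQTL result sets.

GWAS risk variants are linked to eGenes when the variant lies in the
gene's cis window, is in strong LD (r^2 > 0.7 by default) with the gene's
top eQTL/e2QTL variant, and the gene passes the significance filters:
e2QTL-class records require Bonferroni-significant slope response plus a
significant eQTL q-value; eQTL-class records additionally require strong
differential expression (adj. p < 0.05 and |log2FC| > 2).
"""
from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ld_r2
from .datatypes import GenotypeMatrix

RECORD_COLUMNS = [
    "gene_id", "condition", "trait", "gwas_variant", "top_eqtl_variant",
    "ld_r2", "slope", "qval", "de_log2fc", "de_p_adj", "association_class",
]


def gwas_overlap(
    eqtl_results: Mapping[str, pd.DataFrame],
    e2qtl_results: Mapping[str, pd.DataFrame],
    de_results: Mapping[str, pd.DataFrame],
    gwas_hits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    cis_index: pd.DataFrame,
    r2_min: float = 0.7,
    qval_max: float = 0.05,
    de_p_adj_max: float = 0.05,
    de_abs_log2fc_min: float = 2.0,
    gwas_p_max: float = 5e-8,
) -> pd.DataFrame:
    """Trait-association records, one per (gene, trait, condition).

    Parameters
    ----------
    eqtl_results
        Per condition: permutation-pass table (gene_id, variant_id = top
        eQTL, slope, qval).
    e2qtl_results
        Per stimulated condition: slope z-test table with ``significant``.
    de_results
        Per stimulated condition: DE table indexed by gene with ``log2fc``
        and ``p_adj``.
    gwas_hits
        Columns ``variant_id``, ``trait`` and optionally ``p`` (filtered at
        genome-wide significance ``gwas_p_max`` when present).
    cis_index
        (gene_id, variant_id) cis-window membership from
        :func:`e2qtl.eqtl.cis_pairs`.
    """
    hits = gwas_hits.copy()
    if "p" in hits.columns:
        hits = hits[hits["p"] < gwas_p_max]
    cis_lookup = cis_index.groupby("variant_id")["gene_id"].agg(set)

    rows = []
    for _, hit in hits.sort_values(["trait", "variant_id"]).iterrows():
        gv = hit["variant_id"]
        if gv not in genotypes:
            warnings.warn(f"GWAS variant {gv} absent from genotypes; skipped")
            continue
        genes_in_cis = cis_lookup.get(gv, set())
        if not genes_in_cis:
            continue
        for condition in sorted(eqtl_results):
            perm = eqtl_results[condition].set_index("gene_id")
            e2 = e2qtl_results.get(condition)
            e2 = e2.set_index("gene_id") if e2 is not None and len(e2) else None
            de = de_results.get(condition)
            for gene in sorted(genes_in_cis & set(perm.index)):
                rec = perm.loc[gene]
                top_variant = rec["variant_id"]
                if top_variant not in genotypes:
                    continue
                try:
                    r2 = ld_r2(genotypes.column(gv), genotypes.column(top_variant))
                except ValueError:
                    continue
                if not (r2 > r2_min):
                    continue
                sig_eqtl = rec["qval"] < qval_max
                de_lfc = de_padj = np.nan
                if de is not None and gene in de.index:
                    de_lfc = float(de.loc[gene, "log2fc"])
                    de_padj = float(de.loc[gene, "p_adj"])

                is_e2 = (
                    e2 is not None
                    and gene in e2.index
                    and bool(e2.loc[gene, "significant"])
                    and sig_eqtl
                )
                de_pass = (
                    np.isfinite(de_padj)
                    and de_padj < de_p_adj_max
                    and abs(de_lfc) > de_abs_log2fc_min
                )
                is_eqtl = sig_eqtl and de_pass

                if not (is_e2 or is_eqtl):
                    continue
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": condition,
                        "trait": hit["trait"],
                        "gwas_variant": gv,
                        "top_eqtl_variant": top_variant,
                        "ld_r2": r2,
                        "slope": float(rec["slope"]),
                        "qval": float(rec["qval"]),
                        "de_log2fc": de_lfc,
                        "de_p_adj": de_padj,
                        "association_class": "e2qtl" if is_e2 else "eqtl",
                    }
                )
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return out.sort_values(["trait", "gene_id", "condition"], kind="mergesort").reset_index(
        drop=True
    )


def compare_eqtl_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict:
    """Concordance of two eQTL result sets over shared (gene, variant) pairs.

    Returns the Spearman correlation of slopes, the genes whose shared
    pairs all have opposite-sign slopes, and counts.
    """
    a = set_a.set_index(["gene_id", "variant_id"])["slope"]
    b = set_b.set_index(["gene_id", "variant_id"])["slope"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no overlapping (gene, variant) pairs")
    av, bv = a.loc[shared], b.loc[shared]
    if len(shared) > 1 and av.nunique() > 1 and bv.nunique() > 1:
        rho = float(stats.spearmanr(av, bv).statistic)
    else:
        rho = 1.0 if np.sign(av.iloc[0]) == np.sign(bv.iloc[0]) else -1.0
    opposite = av * bv < 0
    per_gene = opposite.groupby(level="gene_id").agg(["all", "any"])
    opposite_genes = sorted(per_gene.index[per_gene["all"]])
    return {
        "spearman": rho,
        "n_shared_pairs": int(len(shared)),
        "n_shared_genes": int(per_gene.shape[0]),
        "opposite_slope_genes": opposite_genes,
        "n_opposite_slope_genes": len(opposite_genes),
    }
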