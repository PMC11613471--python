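"""End-to-end orchestration: simulate -> QC -> DE -> eQTL -> e2QTL ->
GWAS/coloc -> integration, with a deterministic run manifest.

Every stage writes plain-text outputs (TSV/JSON) into the run directory;
given the same configuration and seed the outputs are byte-identical
across runs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import __version__
from .coloc import coloc_abf
from .datatypes import GenotypeMatrix
from .diffexpr import classify_degs, fit_de, normalize_counts
from .eqtl import (
    cis_pairs,
    eqtl_variant_filter,
    nominal_scan,
    permutation_pass_all,
    prepare_expression,
)
from .integrate import compare_eqtl_sets, gwas_overlap
from .qc import expression_outlier_detection, genotype_pca, outlier_sample_ids, variant_qc
from .response import call_response_eqtl, response_summary, select_top_eqtl
from .simulate import (
    GwasTraitSpec,
    SimulationConfig,
    plant_eqtl,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_summary,
)


@dataclass
class GwasConfig:
    """One simulated GWAS trait tied (or not) to a planted eQTL gene."""

    trait: str
    target_gene: str | None = None  # coloc locus; causal variant = gene's planted variant
    causal_variant: str | None = None
    effect: float = 0.0
    n: int = 10_000
    condition: str = "CTRL"  # eQTL condition used for colocalization


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # array-stage variant QC
    maf_min: float = 0.05
    call_rate_min: float = 0.97
    hwe_p_min: float = 1e-4
    # eQTL-stage variant filters
    eqtl_maf_min: float = 0.05
    eqtl_hwe_p_min: float = 1e-6
    # covariates
    n_genotype_pcs: int = 3
    n_expr_factors: int = 5
    # expression QC
    run_outlier_qc: bool = True
    outlier_density_quantile: float = 0.001
    # DE thresholds
    deg_p_adj_max: float = 0.05
    deg_abs_log2fc_min: float = 1.5
    # eQTL permutations
    n_perm_min: int = 1000
    n_perm_max: int = 10000
    qvalue_method: str = "bh"
    # e2QTL: test only genes that are eGenes in the condition pair, so the
    # response set is a subset of the eGene set
    e2qtl_alpha: float = 0.05
    e2qtl_restrict_to_egenes: bool = True
    # integration
    r2_min: float = 0.7
    qval_max: float = 0.05
    integration_de_abs_log2fc_min: float = 2.0
    gwas_p_max: float = 5e-8
    gwas_traits: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        traits = tuple(GwasConfig(**t) for t in raw.pop("gwas_traits", []))
        planted = raw.pop("plant_eqtl", None)
        if planted:
            sim = dataclasses.replace(
                sim,
                planted_eqtl=plant_eqtl(
                    sim,
                    n_eqtl=planted["n_eqtl"],
                    slope_ctrl=planted["slope_ctrl"],
                    slope_stim=planted["slope_stim"],
                ),
            )
        return cls(sim=sim, gwas_traits=traits, **raw)


def _drop_outliers(expr_sets, config):
    """Per condition-pair expression QC; returns cleaned sets + flag table."""
    stimuli = [c for c in config.sim.conditions if c != "CTRL"]
    flags_by_pair = {}
    ctrl_bad: set[str] = set()
    stim_bad: dict[str, set] = {}
    if config.run_outlier_qc and config.sim.n_donors * 2 >= 8:
        for stim in stimuli:
            flags, _ = expression_outlier_detection(
                expr_sets["CTRL"],
                expr_sets[stim],
                density_quantile=config.outlier_density_quantile,
                seed=config.sim.seed,
            )
            flags_by_pair[stim] = flags
            for name in flags.index[flags]:
                donor, cond = name.split("::")
                (ctrl_bad if cond == "CTRL" else stim_bad.setdefault(stim, set())).add(donor)
    cleaned = {"CTRL": expr_sets["CTRL"].drop_samples(sorted(ctrl_bad))}
    for stim in stimuli:
        cleaned[stim] = expr_sets[stim].drop_samples(sorted(stim_bad.get(stim, set())))
    return cleaned, flags_by_pair


def _differential_expression(expr_sets, config):
    """Per-stimulus DE versus control on pooled, jointly normalised counts."""
    stimuli = [c for c in config.sim.conditions if c != "CTRL"]
    de_tables = {}
    for stim in stimuli:
        ctrl, treat = expr_sets["CTRL"], expr_sets[stim]
        pooled = pd.concat(
            [
                ctrl.counts.set_axis([f"{s}::CTRL" for s in ctrl.samples], axis=1),
                treat.counts.set_axis([f"{s}::{stim}" for s in treat.samples], axis=1),
            ],
            axis=1,
        )
        logcpm, _ = normalize_counts(pooled)
        design = pd.DataFrame(
            {"condition": [0] * len(ctrl.samples) + [1] * len(treat.samples)},
            index=logcpm.columns,
        )
        de_tables[stim] = fit_de(logcpm, design)
    return de_tables


def _eqtl_per_condition(genotypes_eqtl, expr_sets, geno_pcs, pairs, config):
    nominal, perm = {}, {}
    for cond in config.sim.conditions:
        es = expr_sets[cond]
        cov = pd.DataFrame(index=es.samples)
        if "sex" in es.sample_covariates.columns:
            cov["sex"] = es.sample_covariates.loc[es.samples, "sex"]
        cov = cov.join(geno_pcs.loc[es.samples])
        prepared = prepare_expression(
            es, covariates=cov, n_expr_factors=config.n_expr_factors
        )
        nominal[cond] = nominal_scan(genotypes_eqtl, prepared, pairs)
        perm[cond] = permutation_pass_all(
            genotypes_eqtl,
            prepared,
            pairs,
            n_perm_min=config.n_perm_min,
            n_perm_max=config.n_perm_max,
            seed=config.sim.seed,
            qvalue_method=config.qvalue_method,
        )
    return nominal, perm


def slope_attenuation_fraction(
    perm_ctrl: pd.DataFrame,
    nominal_stim: pd.DataFrame,
    qval_max: float = 0.05,
) -> float:
    """Among control eGenes, the fraction whose top-variant |slope| shrinks
    upon stimulation."""
    egenes = perm_ctrl[perm_ctrl["qval"] < qval_max]
    stim = nominal_stim.set_index(["gene_id", "variant_id"])
    n_tested = n_reduced = 0
    for _, rec in egenes.iterrows():
        key = (rec["gene_id"], rec["variant_id"])
        if key not in stim.index:
            continue
        n_tested += 1
        if abs(stim.loc[key, "slope"]) < abs(rec["slope"]):
            n_reduced += 1
    return n_reduced / n_tested if n_tested else float("nan")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full chain and write all outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = list(config.sim.conditions)
    stimuli = [c for c in conditions if c != "CTRL"]

    # 1. synthetic study -----------------------------------------------
    genotypes_raw = simulate_genotypes(config.sim)
    expr_sets, truth = simulate_expression(genotypes_raw, config.sim)
    eio.write_dosage_tsv(genotypes_raw, outdir / "genotypes.tsv")
    eio.write_gene_annotation(expr_sets["CTRL"].gene_annotation, outdir / "genes.tsv")
    for cond in conditions:
        eio.write_counts_tsv(expr_sets[cond], outdir / f"counts_{cond}.tsv")
    truth.to_json(outdir / "ground_truth.json")

    # 2. variant QC + genotype PCs --------------------------------------
    genotypes, vqc = variant_qc(
        genotypes_raw,
        maf_min=config.maf_min,
        call_rate_min=config.call_rate_min,
        hwe_p_min=config.hwe_p_min,
    )
    vqc.to_json(outdir / "variant_qc.json")
    geno_pcs = genotype_pca(genotypes, config.n_genotype_pcs)

    # 3. expression outlier QC ------------------------------------------
    expr_sets, outlier_flags = _drop_outliers(expr_sets, config)
    flagged = {
        stim: outlier_sample_ids(flags) for stim, flags in outlier_flags.items()
    }
    with open(outdir / "expression_outliers.json", "w") as fh:
        json.dump(flagged, fh, indent=1, sort_keys=True)

    # 4. differential expression ----------------------------------------
    de_tables = _differential_expression(expr_sets, config)
    for stim, table in de_tables.items():
        eio.write_table(table.reset_index(), outdir / f"de_{stim}.tsv")
    classification, de_summary = classify_degs(
        de_tables,
        p_adj_max=config.deg_p_adj_max,
        abs_log2fc_min=config.deg_abs_log2fc_min,
    )
    eio.write_table(classification.reset_index(), outdir / "deg_classification.tsv")
    eio.write_table(de_summary.reset_index(), outdir / "deg_summary.tsv")

    # 5. cis-eQTL --------------------------------------------------------
    genotypes_eqtl = eqtl_variant_filter(
        genotypes, maf_min=config.eqtl_maf_min, hwe_p_min=config.eqtl_hwe_p_min
    )
    pairs = cis_pairs(expr_sets["CTRL"].gene_annotation, genotypes_eqtl.variants)
    nominal, perm = _eqtl_per_condition(
        genotypes_eqtl, expr_sets, geno_pcs, pairs, config
    )
    for cond in conditions:
        eio.write_table(nominal[cond], outdir / f"eqtl_nominal_{cond}.tsv")
        eio.write_table(perm[cond], outdir / f"eqtl_perm_{cond}.tsv")

    # 6. e2QTL -----------------------------------------------------------
    e2_tables = {}
    e2_summaries = {}
    for stim in stimuli:
        nom_c, nom_s = nominal["CTRL"], nominal[stim]
        if config.e2qtl_restrict_to_egenes:
            egenes_pair = set(
                perm["CTRL"].loc[perm["CTRL"]["qval"] < config.qval_max, "gene_id"]
            ) | set(perm[stim].loc[perm[stim]["qval"] < config.qval_max, "gene_id"])
            nom_c = nom_c[nom_c["gene_id"].isin(egenes_pair)]
            nom_s = nom_s[nom_s["gene_id"].isin(egenes_pair)]
            n_egenes = len(egenes_pair)
        else:
            n_egenes = int((perm[stim]["qval"] < config.qval_max).sum())
        top = select_top_eqtl(nom_c, nom_s)
        e2 = call_response_eqtl(
            top, nom_c, nom_s, condition=stim, alpha=config.e2qtl_alpha
        )
        e2_tables[stim] = e2
        e2_summaries[stim] = response_summary(e2, n_egenes)
        eio.write_table(e2, outdir / f"e2qtl_{stim}.tsv")

    # 7. GWAS + colocalization ------------------------------------------
    gwas_summaries = {}
    coloc_results = {}
    for spec in config.gwas_traits:
        causal = spec.causal_variant
        if causal is None and spec.target_gene is not None:
            for g, v, _ in config.sim.planted_eqtl:
                if g == spec.target_gene:
                    causal = v
                    break
        gwas = simulate_gwas_summary(
            genotypes_raw,
            GwasTraitSpec(trait=spec.trait, causal_variant=causal,
                          effect=spec.effect, n=spec.n),
            seed=config.sim.seed,
        )
        gwas_summaries[spec.trait] = gwas
        eio.write_gwas_tsv(gwas, outdir / f"gwas_{spec.trait}.tsv")
        if spec.target_gene is not None:
            locus_vars = pairs.loc[pairs["gene_id"] == spec.target_gene, "variant_id"]
            nom = nominal[spec.condition]
            eqtl_at_locus = nom[
                (nom["gene_id"] == spec.target_gene)
                & nom["variant_id"].isin(locus_vars)
            ][["variant_id", "slope", "se"]].rename(columns={"slope": "beta"})
            gwas_at_locus = gwas.table[gwas.table["variant_id"].isin(locus_vars)][
                ["variant_id", "beta", "se"]
            ]
            if len(eqtl_at_locus) and len(gwas_at_locus):
                res = coloc_abf(eqtl_at_locus, gwas_at_locus)
                coloc_results[spec.trait] = res
    if coloc_results:
        with open(outdir / "coloc.json", "w") as fh:
            json.dump(
                _jsonable({t: r.as_dict() for t, r in sorted(coloc_results.items())}),
                fh, indent=1, sort_keys=True,
            )

    # 8. integration -----------------------------------------------------
    gwas_hits = pd.concat(
        [
            g.table.assign(trait=t)[["variant_id", "trait", "p"]]
            for t, g in sorted(gwas_summaries.items())
        ],
        ignore_index=True,
    ) if gwas_summaries else pd.DataFrame(columns=["variant_id", "trait", "p"])
    association = gwas_overlap(
        eqtl_results=perm,
        e2qtl_results=e2_tables,
        de_results=de_tables,
        gwas_hits=gwas_hits,
        genotypes=genotypes_eqtl,
        cis_index=pairs,
        r2_min=config.r2_min,
        qval_max=config.qval_max,
        de_p_adj_max=config.deg_p_adj_max,
        de_abs_log2fc_min=config.integration_de_abs_log2fc_min,
        gwas_p_max=config.gwas_p_max,
    )
    eio.write_table(association, outdir / "trait_associations.tsv")

    concordance = {}
    for stim in stimuli:
        try:
            rep = compare_eqtl_sets(nominal["CTRL"], nominal[stim])
        except ValueError:
            continue
        concordance[stim] = {k: v for k, v in rep.items() if k != "opposite_slope_genes"}

    # 9. summary + manifest ---------------------------------------------
    egenes_by_cond = {
        c: sorted(perm[c].loc[perm[c]["qval"] < config.qval_max, "gene_id"])
        for c in conditions
    }
    all_egenes = sorted(set().union(*egenes_by_cond.values())) if egenes_by_cond else []
    e2_genes = sorted(
        set().union(*(set(t.loc[t["significant"], "gene_id"]) for t in e2_tables.values()))
    ) if e2_tables else []
    attenuation = {
        stim: slope_attenuation_fraction(perm["CTRL"], nominal[stim], config.qval_max)
        for stim in stimuli
    }
    summary = {
        "n_deg_total": int((classification["label"] != "none").sum()),
        "deg_per_condition": json.loads(de_summary.to_json(orient="index")),
        "n_egenes_total": len(all_egenes),
        "n_egenes_per_condition": {c: len(v) for c, v in egenes_by_cond.items()},
        "n_e2qtl_genes": len(e2_genes),
        "e2qtl_per_condition": e2_summaries,
        "slope_attenuation_fraction": attenuation,
        "eqtl_concordance": concordance,
        "coloc": {t: r.as_dict() for t, r in sorted(coloc_results.items())},
        "n_trait_association_records": int(len(association)),
    }
    summary = _jsonable(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "seed": config.sim.seed,
        "config": _config_dict(config),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "genotypes": genotypes,
        "de": de_tables,
        "classification": classification,
        "de_summary": de_summary,
        "nominal": nominal,
        "perm": perm,
        "e2qtl": e2_tables,
        "coloc": coloc_results,
        "association": association,
        "summary": summary,
        "truth": truth,
    }


def _jsonable(obj):
    """Recursively convert NaN/inf to None so dumps stay valid JSON."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["planted_eqtl"] = [
        {"gene": g, "variant": v, "slopes": dict(s)} for g, v, s in config.sim.planted_eqtl
    ]
    d["sim"]["conditions"] = list(config.sim.conditions)
    d["gwas_traits"] = [dataclasses.asdict(t) for t in config.gwas_traits]
    return d
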