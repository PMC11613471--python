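# e2qtl

Exposure/response eQTL analysis for paired stimulation designs.

Many gene-regulatory variants only show their effect under a particular
cellular condition. In a paired design — the same donors profiled
unstimulated (control) and after exposure to a stimulus such as a
DNA-damaging agent — such context-specific regulation appears as a change
in the cis-eQTL effect size between conditions. `e2qtl` implements the
full inference chain for detecting these **exposure eQTL (e²QTL)** and
connecting them to disease risk variants:

1. **Variant QC** — MAF, call rate, and an exact conditional
   Hardy–Weinberg test (two-sided by probability ordering).
2. **Expression QC** — PCA + two-component Gaussian-mixture outlier
   detection on pooled control/stimulus samples.
3. **Differential expression** — TMM normalisation, log₂-CPM, per-gene
   linear models with empirical-Bayes variance moderation, BH correction,
   and classification of DEGs into stimulus-specific vs common genes;
   hypergeometric ORA and running-sum GSEA on user-supplied gene sets.
4. **cis-eQTL mapping** — rank-based inverse-normal transform,
   residualisation on sex, genotype PCs and expression PCs, a nominal
   scan of every variant within ±1 Mb of the TSS, and gene-level adjusted
   p-values from an adaptive permutation pass (1,000–10,000 permutations)
   whose minimum p-values are fitted with a Beta(a, b) distribution:

   `p_adj = F_Beta(p_min_observed; a, b)`, with gene-level q-values across genes.
5. **e²QTL detection** — for each eGene's top variant, the slope
   difference z-test

   `z = (β_stim − β_ctrl) / √(se²_stim + se²_ctrl)`,

   two-sided normal p, Bonferroni-corrected per condition pair.
6. **GWAS integration and colocalization** — LD (dosage r²) filtering of
   GWAS risk variants against top eQTL (r² > 0.7), DE filtering for
   eQTL-class associations, and enumeration-based Bayesian colocalization
   with Wakefield approximate Bayes factors:

   `log ABF = ½·log(V/(V+W)) + z²·W / (2(V+W))`,

   yielding posteriors PP.H0–PP.H4 over the shared-causal-variant
   hypotheses.

Because real stimulation-eQTL datasets are access-restricted, the package
ships a **synthetic-data generator** that emulates the whole study design
— LD-blocked genotypes, negative-binomial counts for six conditions
(CTRL, BPDE, HC, MMS, TBOOH, UVC) with a repression-dominated DE
signature, planted cis-eQTL whose slopes attenuate on stimulation, and
GWAS summary statistics that do or do not share a causal variant with an
eQTL — so every stage is testable against planted ground truth.

## Worked example

```python
import dataclasses
from e2qtl.simulate import (SimulationConfig, plant_eqtl,
                            simulate_genotypes, simulate_expression)
from e2qtl.eqtl import (cis_pairs, prepare_expression, nominal_scan,
                        permutation_pass_all)
from e2qtl.response import select_top_eqtl, call_response_eqtl

cfg = SimulationConfig(n_donors=200, n_variants=120, n_genes=60, seed=7,
                       conditions=("CTRL", "UVC"))
cfg = dataclasses.replace(cfg, planted_eqtl=plant_eqtl(cfg, 8,
                          slope_ctrl=1.0, slope_stim=0.4))
genotypes = simulate_genotypes(cfg)
expr, truth = simulate_expression(genotypes, cfg)

pairs = cis_pairs(expr["CTRL"].gene_annotation, genotypes.variants)
scan = {c: permutation_pass_all(genotypes,
                                prepare_expression(expr[c], n_expr_factors=5),
                                pairs, n_perm_min=1000, seed=7)
        for c in cfg.conditions}
nominal = {c: nominal_scan(genotypes,
                           prepare_expression(expr[c], n_expr_factors=5), pairs)
           for c in cfg.conditions}

egenes = set(scan["CTRL"].loc[scan["CTRL"].qval < 0.05, "gene_id"]) \
       | set(scan["UVC"].loc[scan["UVC"].qval < 0.05, "gene_id"])
nom_c = nominal["CTRL"][nominal["CTRL"].gene_id.isin(egenes)]
nom_s = nominal["UVC"][nominal["UVC"].gene_id.isin(egenes)]
top = select_top_eqtl(nom_c, nom_s)
e2 = call_response_eqtl(top, nom_c, nom_s, condition="UVC")
```

Output (eight eQTL planted with control slope 1.0 attenuated to 0.4 on
stimulation):

```
eGenes (qval < 0.05 in either condition): 10
e2QTL (Bonferroni p < 0.05): 5 of 10 tested
 gene_id variant_id  slope_ctrl  slope_stim     z   p_bonf
gene0017   var00034        1.05        0.63 -3.58  0.00339
gene0022   var00044       0.905       0.628  -2.9   0.0376
gene0034   var00069        1.01       0.689 -2.88   0.0398
gene0041   var00081      -0.142       0.471  3.93  0.00086
gene0058   var00117           1       0.575 -4.26 0.000204
```

Slopes are on the inverse-normal scale (effect per alt-allele dosage);
negative z means the effect weakened upon stimulation. Four of the five
calls are planted attenuating eQTL recovered at this sample size;
`gene0041` is a spurious slope-gain call, the kind the Bonferroni
correction keeps rare.

The same chain runs from the shell:

```bash
e2qtl simulate --seed 7 --out study/
e2qtl qc-variants --genotypes study/genotypes.tsv --out qc/
e2qtl pipeline --config pipeline.yaml --out run/
```

`pipeline` executes simulate → QC → DE → eQTL → e²QTL → coloc →
integration and writes per-stage TSVs, a `summary.json` and a run
manifest; outputs are byte-identical across runs with the same config and
seed.

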