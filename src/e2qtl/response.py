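"""Exposure/response eQTL (e2QTL) detection.

For each gene, the most significant cis variant ("top eQTL") is compared
between the unstimulated control and a stimulated condition with a slope
z-test: z = (slope_stim - slope_ctrl) / sqrt(se_stim^2 + se_ctrl^2),
two-sided normal p, Bonferroni-corrected across the genes tested in that
condition pair.
"""
from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special

SELECTION_MODES = ("min_over_conditions", "control_only", "stimulus_only")


def select_top_eqtl(
    eqtl_ctrl: pd.DataFrame,
    eqtl_stim: pd.DataFrame,
    mode: str = "min_over_conditions",
) -> pd.Series:
    """Map gene -> top variant.

    ``eqtl_ctrl`` / ``eqtl_stim`` are nominal-scan tables (gene_id,
    variant_id, distance, p_nominal).  Under the default mode the variant
    with the smallest nominal p across the two conditions wins; ties break
    by smaller |distance| then lexicographic variant_id.  Genes absent from
    either condition are skipped with a warning.
    """
    if mode not in SELECTION_MODES:
        raise ValueError(f"mode must be one of {SELECTION_MODES}")
    genes_ctrl = set(eqtl_ctrl["gene_id"])
    genes_stim = set(eqtl_stim["gene_id"])
    shared = genes_ctrl & genes_stim
    for g in sorted((genes_ctrl | genes_stim) - shared):
        warnings.warn(f"gene {g} absent from one condition; skipped")

    if mode == "control_only":
        pool = eqtl_ctrl
    elif mode == "stimulus_only":
        pool = eqtl_stim
    else:
        pool = pd.concat([eqtl_ctrl, eqtl_stim], ignore_index=True)
    pool = pool[pool["gene_id"].isin(shared)].copy()
    pool["abs_distance"] = pool["distance"].abs()
    pool = pool.sort_values(
        ["gene_id", "p_nominal", "abs_distance", "variant_id"], kind="mergesort"
    )
    top = pool.groupby("gene_id", sort=True).first()["variant_id"]
    top.name = "variant_id"
    return top


def e2qtl_ztest(
    slope_ctrl: float, se_ctrl: float, slope_stim: float, se_stim: float
) -> tuple[float, float]:
    """Slope-difference z-test between two independently estimated eQTL
    effects.  Returns (z, two-sided p)."""
    if se_ctrl <= 0 or se_stim <= 0:
        raise ValueError("standard errors must be positive")
    z = (slope_stim - slope_ctrl) / np.hypot(se_stim, se_ctrl)
    p = 2.0 * special.ndtr(-abs(z))
    return float(z), float(p)


def call_response_eqtl(
    top: pd.Series,
    eqtl_ctrl: pd.DataFrame,
    eqtl_stim: pd.DataFrame,
    condition: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """z-test per gene at its top variant, Bonferroni across tested genes.

    ``eqtl_ctrl`` / ``eqtl_stim`` are nominal tables providing slope and SE
    per (gene, variant).  Genes whose top variant lacks estimates in either
    condition are dropped.  Significance: p_bonf < alpha with n_tests = the
    number of genes tested in this condition pair.
    """
    ic = eqtl_ctrl.set_index(["gene_id", "variant_id"])
    istim = eqtl_stim.set_index(["gene_id", "variant_id"])
    rows = []
    for gene, variant in top.items():
        key = (gene, variant)
        if key not in ic.index or key not in istim.index:
            continue
        c = ic.loc[key]
        s = istim.loc[key]
        if c["se"] <= 0 or s["se"] <= 0:
            continue
        z, p = e2qtl_ztest(c["slope"], c["se"], s["slope"], s["se"])
        rows.append(
            {
                "gene_id": gene,
                "variant_id": variant,
                "condition": condition,
                "slope_ctrl": float(c["slope"]),
                "se_ctrl": float(c["se"]),
                "slope_stim": float(s["slope"]),
                "se_stim": float(s["se"]),
                "delta_slope": float(s["slope"] - c["slope"]),
                "z": z,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "variant_id", "condition", "slope_ctrl", "se_ctrl",
            "slope_stim", "se_stim", "delta_slope", "z", "p",
        ],
    )
    n_tests = len(out)
    out["p_bonf"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    out["significant"] = out["p_bonf"] < alpha
    out.attrs["n_tests"] = n_tests
    return out


def response_summary(e2qtl: pd.DataFrame, n_egenes: int) -> dict:
    """Counts and the fraction of eGenes that are significant e2QTL."""
    n_sig = int(e2qtl["significant"].sum()) if len(e2qtl) else 0
    return {
        "n_tested": int(len(e2qtl)),
        "n_significant": n_sig,
        "fraction_of_egenes": n_sig / n_egenes if n_egenes else float("nan"),
    }
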