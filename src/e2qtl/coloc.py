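"""Linkage disequilibrium from dosages and Bayesian colocalization.

LD is the squared Pearson correlation of dosages (composite LD, phase
free).  Colocalization follows the enumeration scheme over single-causal-
variant configurations with Wakefield approximate Bayes factors: per
variant, log ABF = 0.5 log(V/(V+W)) + z^2 W / (2(V+W)) with V = se^2 and
prior effect variance W; hypothesis sums are accumulated in log space and
converted to posterior probabilities of H0 (no association), H1/H2 (one
trait only), H3 (two distinct causal variants) and H4 (one shared causal
variant).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .datatypes import ColocResult

#: Default prior standard deviation of the effect size: quantitative traits
#: and (log-odds scale) case-control traits.
DEFAULT_PRIOR_SD = {"quant": 0.15, "cc": 0.2}
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are removed pairwise-complete; both vectors must be
    non-constant afterwards and share length >= 3.  Allele-flip invariant.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 pairwise-complete samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def wakefield_abf(beta, se, trait_type: str = "quant", prior_sd: float | None = None):
    """Log approximate Bayes factor for association at each variant."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd is None:
        prior_sd = DEFAULT_PRIOR_SD[trait_type]
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))


def harmonize(trait1: pd.DataFrame, trait2: pd.DataFrame) -> pd.DataFrame:
    """Merge two summary tables on variant_id with matched effect alleles.

    When allele columns are present on both sides, trait-2 betas are
    flipped where effect/other alleles are swapped relative to trait 1;
    variants with irreconcilable alleles are dropped with a warning.
    """
    merged = trait1.merge(trait2, on="variant_id", suffixes=("_1", "_2"))
    has_alleles = {"effect_allele_1", "other_allele_1", "effect_allele_2", "other_allele_2"}
    if has_alleles <= set(merged.columns):
        same = (merged["effect_allele_1"] == merged["effect_allele_2"]) & (
            merged["other_allele_1"] == merged["other_allele_2"]
        )
        flipped = (merged["effect_allele_1"] == merged["other_allele_2"]) & (
            merged["other_allele_1"] == merged["effect_allele_2"]
        )
        bad = ~(same | flipped)
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} variants with mismatched alleles")
            merged = merged[~bad].copy()
            same, flipped = same[~bad], flipped[~bad]
        merged.loc[flipped, "beta_2"] = -merged.loc[flipped, "beta_2"]
    return merged.reset_index(drop=True)


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    trait1_type: str = "quant",
    trait2_type: str = "quant",
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Enumeration colocalization of two traits over shared variants.

    ``trait1`` / ``trait2`` carry ``variant_id``, ``beta``, ``se`` (and
    optionally allele columns, which are harmonized first).  Hypothesis
    weights: H0 = 1, H1 = p1*S1, H2 = p2*S2, H3 = p1*p2*(S1*S2 - S12),
    H4 = p12*S12, where S1/S2/S12 are sums of per-variant (products of)
    ABFs; all sums are carried in log space and H3 is clamped at >= 0.
    """
    merged = harmonize(trait1, trait2)
    if len(merged) == 0:
        raise ValueError("no shared variants between the two traits")
    l1 = wakefield_abf(merged["beta_1"], merged["se_1"], trait1_type, prior_sd1)
    l2 = wakefield_abf(merged["beta_2"], merged["se_2"], trait2_type, prior_sd2)
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)

    lS1 = logsumexp(l1)
    lS2 = logsumexp(l2)
    lS12 = logsumexp(l1 + l2)
    # log(S1*S2 - S12), exactly -inf for a single variant
    lprod = lS1 + lS2
    if lprod > lS12:
        lH3_core = lprod + np.log1p(-np.exp(lS12 - lprod))
    else:
        lH3_core = -np.inf

    lH = np.array(
        [
            0.0,
            np.log(p1) + lS1,
            np.log(p2) + lS2,
            (np.log(p1) + np.log(p2) + lH3_core) if np.isfinite(lH3_core) else -np.inf,
            np.log(p12) + lS12,
        ]
    )
    pp = softmax(lH)
    return ColocResult(
        pp=pp,
        n_variants=len(merged),
        variant_ids=list(merged["variant_id"]),
        log_abf1=l1,
        log_abf2=l2,
        priors=(p1, p2, p12),
    )
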