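"""Variant- and sample-level quality control.

Variant filters mirror standard array QC: minor allele frequency, call
rate, and an exact conditional Hardy-Weinberg equilibrium test (two-sided
by probability ordering).  Sample-level expression QC follows a
PCA + Gaussian-mixture clustering of pooled control/stimulus samples.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datatypes import ExpressionSet, GenotypeMatrix, QcReport


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, the number of heterozygotes
    follows a hypergeometric-type distribution; the p-value is the total
    probability of all heterozygote counts whose probability does not
    exceed that of the observed configuration.

    Returns 1.0 for monomorphic variants (single attainable configuration).
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped sample required")

    n_a = 2 * n_aa + n_Aa  # one allele's count; symmetry makes the choice irrelevant
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0

    # attainable heterozygote counts share the parity of the rare-allele count
    het = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - het) // 2
    hom_common = n - het - hom_rare
    valid = hom_common >= 0
    het, hom_rare, hom_common = het[valid], hom_rare[valid], hom_common[valid]

    # log P(het) up to the shared normalising constant
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(het + 1)
        - gammaln(hom_common + 1)
        + het * np.log(2.0)
    )
    logp -= logsumexp(logp)
    obs = n_Aa
    logp_obs = logp[np.searchsorted(het, obs)]
    # probability ordering with a tolerance for ties under floating point
    p = float(np.exp(logsumexp(logp[logp <= logp_obs + 1e-10])))
    return min(p, 1.0)


def variant_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.97,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep variants with MAF, call rate and HWE p strictly above the
    thresholds; removals are attributed to the first failing filter
    (order: MAF, call rate, HWE)."""
    if genotypes.n_variants == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    for name, val, hi in (
        ("maf_min", maf_min, 0.5),
        ("call_rate_min", call_rate_min, 1.0),
        ("hwe_p_min", hwe_p_min, 1.0),
    ):
        if not (0 <= val <= hi):
            raise ValueError(f"{name} outside valid range")

    maf = genotypes.maf()
    call_rate = genotypes.call_rate()
    gcounts = genotypes.genotype_counts()
    hwe_p = np.array([
        hwe_exact_test(int(a), int(b), int(c)) if (a + b + c) > 0 else 0.0
        for a, b, c in gcounts
    ])

    pass_maf = maf > maf_min
    pass_cr = call_rate > call_rate_min
    pass_hwe = hwe_p > hwe_p_min
    keep = pass_maf & pass_cr & pass_hwe

    removed = {
        "maf": int((~pass_maf).sum()),
        "call_rate": int((pass_maf & ~pass_cr).sum()),
        "hwe": int((pass_maf & pass_cr & ~pass_hwe).sum()),
    }
    report = QcReport(
        n_input=genotypes.n_variants,
        n_pass=int(keep.sum()),
        removed=removed,
        details={
            "thresholds": {
                "maf_min": maf_min,
                "call_rate_min": call_rate_min,
                "hwe_p_min": hwe_p_min,
            }
        },
    )
    return genotypes.subset_variants(keep), report


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean."""
    if not np.isnan(dosages).any():
        return dosages
    out = dosages.copy()
    col_mean = np.nanmean(out, axis=0)
    r, c = np.where(np.isnan(out))
    out[r, c] = col_mean[c]
    return out


def genotype_pca(genotypes: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k PCs of the mean-imputed, column-standardised dosage matrix.

    Scores are orthogonal; each component's sign is fixed so that its
    largest-magnitude variant loading is positive.
    """
    n, m = genotypes.n_samples, genotypes.n_variants
    if k < 0 or k >= min(n, m):
        if k != 0:
            raise ValueError("k must satisfy 0 <= k < min(n_samples, n_variants)")
    X = mean_impute(genotypes.dosages)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    if not nonconst.any():
        raise ValueError("all variants constant; PCA undefined")
    X = X[:, nonconst] / sd[nonconst]
    if k == 0:
        return pd.DataFrame(np.empty((n, 0)), index=genotypes.samples)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=genotypes.samples,
                        columns=[f"PC{j + 1}" for j in range(k)])


def expression_outlier_detection(
    counts_control: ExpressionSet,
    counts_stimulus: ExpressionSet,
    density_quantile: float = 0.001,
    seed: int = 0,
    min_cpm: float = 1.0,
    min_frac: float = 0.2,
) -> tuple[pd.Series, QcReport]:
    """Flag aberrant samples in a pooled control + single-stimulus PCA.

    Log-CPM of the pooled samples is reduced to its top two PCs and
    modelled with a two-component full-covariance Gaussian mixture
    (k-means initialisation, fixed seed).  A sample is flagged when it
    falls in the low-density tail of the fitted mixture (squared
    Mahalanobis distance to every component beyond the chi-square(2)
    quantile at ``1 - density_quantile``), or when it is not assigned to
    the cluster that dominates its own condition.  Deterministic given the
    seed; invariant to sample order (samples are canonically sorted before
    fitting).
    """
    from sklearn.mixture import GaussianMixture

    from .diffexpr import normalize_counts

    ctrl_names = [f"{s}::{counts_control.condition}" for s in counts_control.samples]
    stim_names = [f"{s}::{counts_stimulus.condition}" for s in counts_stimulus.samples]
    shared_genes = counts_control.counts.index.intersection(counts_stimulus.counts.index)
    pooled = pd.concat(
        [
            counts_control.counts.loc[shared_genes].set_axis(ctrl_names, axis=1),
            counts_stimulus.counts.loc[shared_genes].set_axis(stim_names, axis=1),
        ],
        axis=1,
    )
    n_total = pooled.shape[1]
    if n_total < 8:
        raise ValueError("need at least 8 pooled samples for outlier detection")
    if n_total < 2:
        raise ValueError("fewer samples than mixture components")

    # canonical sample order for order-invariance
    order = sorted(pooled.columns)
    pooled = pooled[order]
    condition = pd.Series(
        [name.split("::")[1] for name in order], index=order, name="condition"
    )

    logcpm, _ = normalize_counts(pooled, min_cpm=min_cpm, min_frac=min_frac)
    Y = logcpm.T.to_numpy()
    Y = Y - Y.mean(axis=0)
    total_var = float((Y**2).sum())
    flags = pd.Series(False, index=order)
    if total_var < 1e-10:  # degenerate: all samples identical
        report = QcReport(n_input=n_total, n_pass=n_total, removed={"outlier": 0},
                          details={"degenerate": True})
        return flags, report

    U, S, _ = np.linalg.svd(Y, full_matrices=False)
    pcs = U[:, :2] * S[:2]

    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-6,
        n_init=1,
    ).fit(pcs)
    labels = gmm.predict(pcs)

    # low-density tail of the fitted mixture: beyond the chi-square(2)
    # contour enclosing 1 - density_quantile mass of every component
    from scipy.stats import chi2

    thresh = chi2.ppf(1.0 - density_quantile, df=2)
    mahal2 = np.full(n_total, np.inf)
    for k in range(gmm.n_components):
        diff = pcs - gmm.means_[k]
        prec = np.linalg.inv(gmm.covariances_[k])
        mahal2 = np.minimum(mahal2, np.einsum("ij,jk,ik->i", diff, prec, diff))
    low_density = mahal2 > thresh

    # condition-cluster pattern: each condition's dominant cluster is the
    # one holding most of its samples; a sample outside its condition's
    # dominant cluster does not fit the design
    dominant = {
        cond: int(pd.Series(labels[(condition == cond).to_numpy()]).mode().iloc[0])
        for cond in condition.unique()
    }
    mismatch = np.array(
        [labels[i] != dominant[condition.iloc[i]] for i in range(n_total)]
    )

    out = low_density | mismatch
    flags[:] = out
    report = QcReport(
        n_input=n_total,
        n_pass=int((~out).sum()),
        removed={"outlier": int(out.sum())},
        details={
            "pc_coordinates": {s: [float(pcs[i, 0]), float(pcs[i, 1])] for i, s in enumerate(order)},
            "cluster": {s: int(labels[i]) for i, s in enumerate(order)},
            "rule": {"density_quantile": density_quantile},
        },
    )
    return flags, report


def outlier_sample_ids(flags: pd.Series) -> list[str]:
    """Donor ids (without the condition suffix) of flagged samples."""
    return sorted({name.split("::")[0] for name, f in flags.items() if f})
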