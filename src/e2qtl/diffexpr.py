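"""Differential expression and gene-set enrichment.

Implements the standard bulk RNA-seq linear-model workflow natively:
TMM library-size normalisation, log2-CPM with a library-size-scaled prior
count, per-gene linear models with empirical-Bayes variance moderation
(moment-matching estimation of the prior degrees of freedom and prior
variance), Benjamini-Hochberg correction, DEG classification into
stimulus-specific vs common genes, hypergeometric over-representation
analysis, and a weighted Kolmogorov-Smirnov running-sum GSEA with a
gene-label permutation null.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# normalisation
# --------------------------------------------------------------------------

def tmm_norm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile (of depth-scaled
    counts) is closest to the mean upper-quartile.  For each sample,
    gene-wise log-ratios M and average abundances A versus the reference
    are trimmed (30% of M, 5% of A by default) and the factor is the
    weighted mean of the remaining M values, with inverse asymptotic-
    variance weights.  Factors are normalised to unit geometric mean.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("sample with zero total counts")
    scaled = counts / lib
    uq = scaled.quantile(0.75)
    ref = (uq - uq.mean()).abs().idxmin()

    x_ref = counts[ref].to_numpy(dtype=float)
    n_ref = lib[ref]
    factors = {}
    for s in counts.columns:
        x = counts[s].to_numpy(dtype=float)
        n = lib[s]
        ok = (x > 0) & (x_ref > 0)
        if ok.sum() == 0:
            factors[s] = 1.0
            continue
        xr, rr = x[ok] / n, x_ref[ok] / n_ref
        M = np.log2(xr / rr)
        A = 0.5 * np.log2(xr * rr)
        w = (n - x[ok]) / (n * x[ok]) + (n_ref - x_ref[ok]) / (n_ref * x_ref[ok])
        k = len(M)
        loM, hiM = np.floor(k * logratio_trim) + 1, k - np.floor(k * logratio_trim)
        loA, hiA = np.floor(k * abs_expr_trim) + 1, k - np.floor(k * abs_expr_trim)
        rM = stats.rankdata(M, method="ordinal")
        rA = stats.rankdata(A, method="ordinal")
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() == 0 or np.isclose(np.abs(M).max(), 0):
            factors[s] = 1.0
        else:
            factors[s] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.log(f).mean())
    return f


def normalize_counts(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_frac: float = 0.2,
    prior_count: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter lowly-expressed genes, compute TMM factors and log2-CPM.

    Genes are kept when their raw CPM reaches ``min_cpm`` in at least
    ``min_frac`` of samples.  The prior count is scaled per sample in
    proportion to effective library size, which makes log-CPM exactly
    depth-invariant for proportional samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    cpm_raw = counts / lib * 1e6
    keep = (cpm_raw >= min_cpm).mean(axis=1) >= min_frac
    filtered = counts.loc[keep]
    factors = tmm_norm_factors(filtered)
    eff_lib = filtered.sum(axis=0).astype(float) * factors
    prior = prior_count * eff_lib / eff_lib.mean()
    logcpm = np.log2((filtered + prior) / (eff_lib + 2 * prior) * 1e6)
    return logcpm, factors


# --------------------------------------------------------------------------
# moderated-t differential expression
# --------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F prior for residual variances.

    Returns (d0, s0_sq): prior degrees of freedom (may be inf) and prior
    variance, estimated from the moments of log sample variances.
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def fit_de(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    coef: str = "condition",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression.

    ``design`` is samples x covariates (must include a ``coef`` column,
    typically a 0/1 stimulus indicator; an intercept is added).  Residual
    variances are shrunk toward a common prior estimated by moment
    matching; the moderated t has ``df_residual + d0`` degrees of freedom.
    Set ``prior_df=np.inf`` to force complete pooling to the common
    variance.
    """
    samples = list(logcpm.columns)
    X = np.column_stack([np.ones(len(samples)), design.loc[samples].to_numpy(dtype=float)])
    cols = ["intercept"] + list(design.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is confounded (rank deficient)")
    j = cols.index(coef)
    groups = design.loc[samples, coef]
    if groups.nunique() == 2 and groups.value_counts().min() < 2:
        raise ValueError("need at least 2 samples per group")

    Y = logcpm.to_numpy(dtype=float)  # genes x samples
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - B @ X.T
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = (resid**2).sum(axis=1) / df
    c_jj = xtx_inv[j, j]

    if prior_df is None:
        d0, s0_sq = fit_f_dist(s2, df)
    else:
        d0 = prior_df
        s0_sq = float(np.mean(s2)) if np.isinf(prior_df) else fit_f_dist(s2, df)[1]
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        post_var = (df * s2 + d0 * s0_sq) / (df + d0)
        df_total = df + d0

    coef_hat = B[:, j]
    se = np.sqrt(post_var * c_jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef_hat / se, np.sign(coef_hat) * np.inf)
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(np.isnan(pvals) & (np.abs(t) == np.inf), 0.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)

    out = pd.DataFrame(
        {
            "gene_id": logcpm.index,
            "log2fc": coef_hat,
            "t_moderated": t,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
            "mean_expr": Y.mean(axis=1),
        }
    ).set_index("gene_id")
    return out


def classify_degs(
    de_tables: Mapping[str, pd.DataFrame],
    p_adj_max: float = 0.05,
    abs_log2fc_min: float = 1.5,
    common_rule: str = "two_or_more",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify genes as stimulus-specific / common / not significant.

    Significance per condition is strict: ``p_adj < p_adj_max`` and
    ``|log2fc| > abs_log2fc_min``.  ``common_rule`` is ``"two_or_more"``
    (default: significant in at least two stimuli) or ``"all"``.
    Also returns per-condition up/down counts and the down-fraction.
    """
    if common_rule not in ("two_or_more", "all"):
        raise ValueError("common_rule must be 'two_or_more' or 'all'")
    conditions = sorted(de_tables)
    genes = de_tables[conditions[0]].index
    for c in conditions:
        if not de_tables[c].index.equals(genes):
            de_tables = {c: t.reindex(genes) for c, t in de_tables.items()}
            break

    sig = {}
    summary_rows = []
    for c in conditions:
        t = de_tables[c]
        s = (t["p_adj"] < p_adj_max) & (t["log2fc"].abs() > abs_log2fc_min)
        sig[c] = s.fillna(False)
        n_down = int((s & (t["log2fc"] < 0)).sum())
        n_up = int((s & (t["log2fc"] > 0)).sum())
        tot = n_down + n_up
        summary_rows.append(
            {
                "condition": c,
                "n_deg": tot,
                "n_down": n_down,
                "n_up": n_up,
                "fraction_down": n_down / tot if tot else np.nan,
            }
        )
    sig_df = pd.DataFrame(sig)
    n_sig = sig_df.sum(axis=1)
    n_cond = len(conditions)
    common_min = 2 if common_rule == "two_or_more" else n_cond
    label = np.where(
        n_sig == 0, "none", np.where(n_sig == 1, "specific",
                                     np.where(n_sig >= common_min, "common", "specific"))
    )
    # under the "all" rule, genes significant in >1 but <all stimuli keep
    # the "specific" label only when exactly one; otherwise unclassified
    if common_rule == "all":
        label = np.where((n_sig > 1) & (n_sig < n_cond), "multi", label)
    classification = pd.DataFrame(
        {
            "significant_in": [
                ",".join(c for c in conditions if sig_df.loc[g, c]) for g in genes
            ],
            "n_significant": n_sig,
            "label": label,
        },
        index=genes,
    )
    return classification, pd.DataFrame(summary_rows).set_index("condition")


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------

def ora(selected: Sequence[str], annotation_set: Sequence[str], universe: Sequence[str]) -> dict:
    """Hypergeometric over-representation: P(overlap >= observed)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    annot = set(annotation_set) & universe
    overlap = len(selected & annot)
    M, K, n = len(universe), len(annot), len(selected)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
    return {"overlap": overlap, "p": min(p, 1.0), "set_size": K, "n_selected": n}


def ora_table(
    selected: Sequence[str], gene_sets: Mapping[str, Sequence[str]], universe: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for set_id in sorted(gene_sets):
        r = ora(selected, gene_sets[set_id], universe)
        r["set_id"] = set_id
        rows.append(r)
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = bh_adjust(out["p"])
    return out


def _running_es(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the GSEA running sum."""
    nh = hit_mask.sum()
    n = len(hit_mask)
    if nh == 0 or nh == n:
        return 0.0
    wsum = weights[hit_mask].sum()
    step = np.where(hit_mask, weights / wsum if wsum > 0 else 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked_scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted KS running-sum enrichment with a gene-label permutation null.

    Genes are ordered by decreasing score; hits advance the running sum in
    proportion to |score|^weight (normalised over hits) and misses retreat
    it by 1/(N - Nh).  The enrichment score (ES) is the maximum deviation;
    NES normalises by the mean magnitude of same-sign permutation scores,
    and p-values are one-sided within the same-sign permutations.  Sets
    with no overlap with the ranking are skipped with a warning.
    """
    if ranked_scores.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    order = ranked_scores.sort_values(ascending=False, kind="mergesort")
    genes = np.asarray(order.index)
    weights = np.abs(order.to_numpy(dtype=float)) ** weight
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for set_id in sorted(gene_sets):
        members = [g for g in gene_sets[set_id] if g in gene_pos]
        if not members:
            warnings.warn(f"gene set {set_id} has no overlap with the ranking; skipped")
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[gene_pos[g] for g in members]] = True
        es = _running_es(hit, weights)

        nh = hit.sum()
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=nh, replace=False)] = True
            perm_es[b] = _running_es(mask, weights)
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same) == 0:
            p = 1.0 / (1.0 + n_perm)
            nes = np.nan
        else:
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
            denom = np.mean(np.abs(same))
            nes = es / denom if denom > 0 else np.nan
        rows.append(
            {"set_id": set_id, "overlap": int(nh), "es": es, "nes": nes, "p": p}
        )
    out = pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["overlap", "es", "nes", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out
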