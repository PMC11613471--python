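"""Per-condition cis-eQTL mapping.

The scan follows the standard gene-level permutation scheme: expression is
filtered, rank-based inverse-normal transformed per gene, residualised on
covariates (sex, top genotype PCs, top expression PCs as hidden-factor
surrogates), then each gene is regressed on every variant within a 1 Mb
cis window of its TSS.  Gene-level adjusted p-values come from an adaptive
permutation pass (1,000 to 10,000 permutations of the expression vector)
whose minimum nominal p-values are fitted with a Beta(a, b) distribution;
the beta CDF evaluated at the observed minimum gives the adjusted p, and
gene-level q-values are computed across genes.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import BetaNullFit, ExpressionSet, GenotypeMatrix
from .diffexpr import bh_adjust, normalize_counts
from .qc import mean_impute

CIS_WINDOW = 1_000_000


# --------------------------------------------------------------------------
# expression preparation
# --------------------------------------------------------------------------

@dataclass
class PreparedExpression:
    """Residualised inverse-normal expression ready for the scan."""

    data: pd.DataFrame  # samples x genes
    n_covariates: int
    covariate_names: list

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def genes(self) -> list:
        return list(self.data.columns)


def inverse_normal_transform(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Rank-based inverse normal: rank r -> Phi^-1((r - 0.5) / n), average
    ranks for ties.  Invariant to any monotone distortion of the input."""
    ranks = stats.rankdata(values, method="average", axis=axis)
    n = values.shape[axis]
    return special.ndtri((ranks - 0.5) / n)


def prepare_expression(
    counts: ExpressionSet,
    covariates: pd.DataFrame | None = None,
    n_expr_factors: int = 15,
    min_cpm: float = 1.0,
    min_frac: float = 0.2,
) -> PreparedExpression:
    """Filter, inverse-normal transform, and residualise expression.

    ``covariates`` is samples x covariates (e.g. sex and genotype PCs);
    hidden expression factors are the top ``n_expr_factors`` PCs of the
    transformed matrix and are appended to the covariates before
    residualisation.  The output is re-centred per gene.
    """
    logcpm, _ = normalize_counts(counts.counts, min_cpm=min_cpm, min_frac=min_frac)
    samples = list(logcpm.columns)
    Z = inverse_normal_transform(logcpm.T.to_numpy(dtype=float), axis=0)  # samples x genes

    n = len(samples)
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[samples].to_numpy(dtype=float)
        parts.append(cov)
        names += list(covariates.columns)
    k = min(n_expr_factors, max(0, min(n, Z.shape[1]) - 1))
    if k > 0:
        Zc = Z - Z.mean(axis=0)
        U, S, _ = np.linalg.svd(Zc, full_matrices=False)
        parts.append(U[:, :k] * S[:k])
        names += [f"ExprPC{i + 1}" for i in range(k)]
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates are collinear (with the intercept or each other)")
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    resid = resid - resid.mean(axis=0)
    data = pd.DataFrame(resid, index=samples, columns=logcpm.index)
    return PreparedExpression(data=data, n_covariates=X.shape[1] - 1, covariate_names=names[1:])


# --------------------------------------------------------------------------
# cis pairing
# --------------------------------------------------------------------------

def cis_pairs(
    genes: pd.DataFrame, variants: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """All (gene, variant) pairs with |pos - tss| <= window (inclusive),
    same chromosome.  ``genes`` is indexed by gene_id with ``chrom`` and
    ``tss`` columns; distance is signed as pos - tss (1-based positions).
    Genes without a TSS are skipped with a warning.
    """
    missing_tss = genes.index[genes["tss"].isna()] if "tss" in genes else genes.index
    if "tss" not in genes.columns:
        raise ValueError("gene annotation lacks a 'tss' column")
    for g in missing_tss:
        warnings.warn(f"gene {g} has no TSS; skipped from cis pairing")
    g = genes.dropna(subset=["tss"]).reset_index()
    gene_col = g.columns[0]
    v = variants[["variant_id", "chrom", "pos"]]
    merged = g.merge(v, on="chrom")
    merged["distance"] = merged["pos"].astype(int) - merged["tss"].astype(int)
    merged = merged[merged["distance"].abs() <= window]
    out = merged[[gene_col, "variant_id", "distance"]].rename(columns={gene_col: "gene_id"})
    return out.sort_values(["gene_id", "distance"], kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# nominal scan
# --------------------------------------------------------------------------

def eqtl_variant_filter(
    genotypes: GenotypeMatrix, maf_min: float = 0.05, hwe_p_min: float = 1e-6
) -> GenotypeMatrix:
    """Apply the eQTL-stage variant filters (MAF and HWE, strict >)."""
    from .qc import variant_qc

    filtered, _ = variant_qc(
        genotypes, maf_min=maf_min, call_rate_min=0.0, hwe_p_min=hwe_p_min
    )
    return filtered


def _gene_block(genotypes, prepared, pair_sub):
    """Centered dosage block and bookkeeping for one gene's cis variants."""
    vids = [v for v in pair_sub["variant_id"] if v in genotypes]
    if not vids:
        return None
    idx = [genotypes._index[v] for v in vids]
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    rows = [sample_pos[s] for s in prepared.samples]
    G = mean_impute(genotypes.dosages)[np.ix_(rows, idx)]
    Gc = G - G.mean(axis=0)
    sxx = (Gc**2).sum(axis=0)
    ok = sxx > 1e-12
    if not ok.any():
        return None
    dist = pair_sub.set_index("variant_id").loc[vids, "distance"].to_numpy()
    return Gc[:, ok], sxx[ok], [v for v, o in zip(vids, ok) if o], dist[ok]


def _slope_se_p(y: np.ndarray, Gc: np.ndarray, sxx: np.ndarray, df: int):
    syy = float((y**2).sum())
    sxy = Gc.T @ y
    slope = sxy / sxx
    rss = np.maximum(syy - slope * sxy, 0.0)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), 0.0, p)
    return slope, se, p


def _df_resid(prepared: PreparedExpression, adjust_df: bool) -> int:
    n = len(prepared.samples)
    df = n - 2 - (prepared.n_covariates if adjust_df else 0)
    if df < 1:
        raise ValueError("not enough samples for the scan")
    return df


def nominal_scan(
    genotypes: GenotypeMatrix,
    prepared: PreparedExpression,
    pairs: pd.DataFrame,
    adjust_df: bool = True,
) -> pd.DataFrame:
    """Simple regression of residualised expression on dosage per cis pair.

    Covariates were projected out in :func:`prepare_expression`; by default
    the t-test degrees of freedom are reduced accordingly.  Zero-variance
    variants are skipped.  Requires >= 10 samples.
    """
    if len(prepared.samples) < 10:
        raise ValueError("need at least 10 samples")
    df = _df_resid(prepared, adjust_df)
    out = []
    for gene, sub in pairs.groupby("gene_id", sort=True):
        if gene not in prepared.data.columns:
            continue
        block = _gene_block(genotypes, prepared, sub)
        if block is None:
            continue
        Gc, sxx, vids, dist = block
        y = prepared.data[gene].to_numpy(dtype=float)
        slope, se, p = _slope_se_p(y, Gc, sxx, df)
        out.append(
            pd.DataFrame(
                {
                    "gene_id": gene,
                    "variant_id": vids,
                    "distance": dist.astype(int),
                    "slope": slope,
                    "se": se,
                    "p_nominal": p,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "distance", "slope", "se", "p_nominal"]
        )
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# permutation pass with beta approximation
# --------------------------------------------------------------------------

def _fit_beta(minima: np.ndarray) -> tuple[float, float]:
    """Fit Beta(a, b) to permutation minima: MLE with method-of-moments
    initialisation; falls back to the moment estimates if the optimiser
    fails."""
    x = np.clip(minima, 1e-300, 1 - 1e-12)
    m, v = x.mean(), x.var()
    if v <= 0:
        return 1.0, 1.0
    common = m * (1 - m) / v - 1.0
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    lx, l1x = np.log(x).mean(), np.log1p(-x).mean()

    def negll(params):
        a, b = np.exp(params)
        return -((a - 1) * lx + (b - 1) * l1x - special.betaln(a, b))

    try:
        res = optimize.minimize(negll, np.log([a0, b0]), method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500})
        if res.success or res.fun < negll(np.log([a0, b0])):
            a, b = np.exp(res.x)
            return float(a), float(b)
    except Exception:  # pragma: no cover - defensive
        pass
    return float(a0), float(b0)


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene stream independent of processing order."""
    return np.random.default_rng([seed, zlib.crc32(gene_id.encode()) & 0x7FFFFFFF])


def _perm_min_p(y, Gc, sxx, df, n_perm, rng):
    """Minimum nominal p across cis variants for each permutation of y."""
    P = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    sxy = P @ Gc  # n_perm x m
    syy = float((y**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx[None, :] * syy)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    tstat2 = df * r2 / (1.0 - r2)
    # monotone map: largest t^2 <-> smallest p; evaluate p only at the max
    return 2 * stats.t.sf(np.sqrt(tstat2.max(axis=1)), df)


def permutation_pass(
    genotypes: GenotypeMatrix,
    prepared: PreparedExpression,
    pairs: pd.DataFrame,
    gene_id: str,
    n_perm_min: int = 1000,
    n_perm_max: int = 10000,
    seed: int = 0,
    adaptive_min_hits: int = 10,
    adjust_df: bool = True,
) -> tuple[dict, BetaNullFit]:
    """Gene-level adjusted p by adaptive permutation + beta approximation.

    Runs ``n_perm_min`` permutations of the expression vector; if fewer
    than ``adaptive_min_hits`` permutation minima reach the observed
    minimum, continues to ``n_perm_max``.  Returns the top-variant record
    (ties broken by smaller |distance|, then variant_id) with
    ``p_perm_beta`` from the fitted beta CDF and the direct plus-one
    permutation p-value.
    """
    if n_perm_min < 100:
        raise ValueError("n_perm_min must be at least 100")
    if n_perm_max < n_perm_min:
        raise ValueError("n_perm_max must be >= n_perm_min")
    sub = pairs[pairs["gene_id"] == gene_id]
    if len(sub) == 0:
        raise ValueError(f"gene {gene_id} has no cis variants")
    block = _gene_block(genotypes, prepared, sub)
    if block is None:
        raise ValueError(f"gene {gene_id} has no usable cis variants")
    Gc, sxx, vids, dist = block
    df = _df_resid(prepared, adjust_df)
    y = prepared.data[gene_id].to_numpy(dtype=float)

    slope, se, p = _slope_se_p(y, Gc, sxx, df)
    order = np.lexsort((vids, np.abs(dist), p))
    top = order[0]
    obs_min = float(p[top])

    rng = _gene_rng(seed, gene_id)
    minima = _perm_min_p(y, Gc, sxx, df, n_perm_min, rng)
    hits = int((minima <= obs_min).sum())
    if hits < adaptive_min_hits and n_perm_max > n_perm_min:
        extra = _perm_min_p(y, Gc, sxx, df, n_perm_max - n_perm_min, rng)
        minima = np.concatenate([minima, extra])
        hits = int((minima <= obs_min).sum())
    n_perm = len(minima)
    p_direct = (1.0 + hits) / (1.0 + n_perm)

    a, b = _fit_beta(minima)
    p_beta = float(stats.beta.cdf(obs_min, a, b))
    p_beta = max(p_beta, 1e-300)

    record = {
        "gene_id": gene_id,
        "variant_id": vids[top],
        "distance": int(dist[top]),
        "slope": float(slope[top]),
        "se": float(se[top]),
        "p_nominal": obs_min,
        "p_perm_beta": p_beta,
        "p_perm_direct": p_direct,
        "n_perm": n_perm,
    }
    fit = BetaNullFit(a=a, b=b, n_perm_used=n_perm, empirical_pperm=p_direct)
    return record, fit


def permutation_pass_all(
    genotypes: GenotypeMatrix,
    prepared: PreparedExpression,
    pairs: pd.DataFrame,
    n_perm_min: int = 1000,
    n_perm_max: int = 10000,
    seed: int = 0,
    qvalue_method: str = "bh",
    adjust_df: bool = True,
) -> pd.DataFrame:
    """Permutation pass over every gene with cis variants, plus q-values."""
    records = []
    for gene in sorted(pairs["gene_id"].unique()):
        if gene not in prepared.data.columns:
            continue
        try:
            rec, fit = permutation_pass(
                genotypes, prepared, pairs, gene,
                n_perm_min=n_perm_min, n_perm_max=n_perm_max, seed=seed,
                adjust_df=adjust_df,
            )
        except ValueError:
            continue
        rec["beta_a"] = fit.a
        rec["beta_b"] = fit.b
        records.append(rec)
    if not records:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "distance", "slope", "se", "p_nominal",
                     "p_perm_beta", "p_perm_direct", "n_perm", "beta_a", "beta_b", "qval"]
        )
    out = pd.DataFrame(records)
    out["qval"] = compute_qvalues(out["p_perm_beta"], method=qvalue_method)
    return out


def compute_qvalues(p, method: str = "bh") -> np.ndarray:
    """Gene-level q-values: BH by default, or Storey with pi0 estimated at
    lambda = 0.5 (``pi0 = min(1, mean(p > 0.5) / 0.5)``)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    q = bh_adjust(p)
    if method == "bh":
        return q
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if len(p) else 1.0
        pi0 = max(pi0, 1.0 / len(p))
        return np.minimum(q * pi0, 1.0)
    raise ValueError("method must be 'bh' or 'storey'")
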