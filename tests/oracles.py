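"""Independent reference implementations used only by the tests.

These deliberately use different algorithms/arithmetic from the package:
exact rational enumeration for the HWE test, literal step-up recursion for
BH, and explicit enumeration over causal-variant configurations for
colocalization.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    probs = {}
    total = Fraction(0)
    for het in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        if hom_common < 0:
            continue
        # multinomial configurations x 2^het, over a shared denominator
        w = Fraction(
            comb(n, hom_rare) * comb(n - hom_rare, het) * (2**het)
        )
        probs[het] = w
        total += w
    p_obs = probs[n_Aa] / total
    p = sum(w for w in probs.values() if w / total <= p_obs) / total
    return float(min(p, Fraction(1)))


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return adj


def coloc_enumeration_oracle(
    log_abf1: np.ndarray,
    log_abf2: np.ndarray,
    p1: float,
    p2: float,
    p12: float,
) -> np.ndarray:
    """Posterior probabilities by direct summation over all causal
    configurations (feasible for small variant counts)."""
    bf1 = np.exp(np.asarray(log_abf1, dtype=float))
    bf2 = np.exp(np.asarray(log_abf2, dtype=float))
    m = len(bf1)
    h0 = 1.0
    h1 = p1 * bf1.sum()
    h2 = p2 * bf2.sum()
    h3 = 0.0
    h4 = 0.0
    for i in range(m):
        for j in range(m):
            if i == j:
                h4 += p12 * bf1[i] * bf2[i]
            else:
                h3 += p1 * p2 * bf1[i] * bf2[j]
    w = np.array([h0, h1, h2, h3, h4])
    return w / w.sum()


def ols_slope_se(y: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope, SE and two-sided p by the closed form."""
    from scipy import stats

    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    slope = float(gc @ yc) / sxx
    rss = float(yc @ yc) - slope**2 * sxx
    df = n - 2
    se = np.sqrt(rss / df / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), df)
    return slope, float(se), float(p)


def marginal_scan(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-column simple regression (slope, se, p)."""
    from scipy import stats

    y = np.asarray(y, float)
    G = np.asarray(G, float)
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    slope = gc.T @ yc / sxx
    rss = float(yc @ yc) - slope**2 * sxx
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0) / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return slope, se, p
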