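"""Core in-memory containers shared across pipeline stages.

Genotypes are held as alt-allele dosages (0/1/2, NaN = missing) in a
samples x variants array with a variant metadata table; expression is held
per condition as a genes x samples count matrix together with gene
annotation (chromosome, TSS) and per-sample covariates.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


class GenotypeMatrix:
    """Donors x variants alt-allele dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array of dosages in {0, 1, 2};
        missing calls are NaN.
    samples
        Sample (donor) identifiers, one per row.
    variants
        Table with at least ``variant_id, chrom, pos, ref, alt`` columns.
        Positions are 1-based.
    sim_params
        Optional generator bookkeeping (per-variant allele frequencies, LD
        block layout) carried along so that additional cohorts can be drawn
        from the same population model.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        samples: Sequence[str],
        variants: pd.DataFrame,
        sim_params: dict | None = None,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if dosages.shape[0] != len(samples):
            raise ValueError("sample count does not match dosage rows")
        if dosages.shape[1] != len(variants):
            raise ValueError("variant count does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        if variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id in variant table")
        self.dosages = dosages
        self.samples = list(samples)
        self.variants = variants.reset_index(drop=True)
        self.sim_params = sim_params or {}
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant (may contain NaN)."""
        return self.dosages[:, self._index[variant_id]]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    # -- per-variant summaries ------------------------------------------
    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to the nearest genotype class (NaN preserved)."""
        return np.clip(np.round(self.dosages), 0, 2)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of hom-ref / het / hom-alt hard calls."""
        hc = self.hard_calls()
        out = np.empty((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(hc == g, axis=0)
        return out

    # -- subsetting ------------------------------------------------------
    def subset_variants(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = np.asarray([self._index[v] for v in keep])
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.samples,
            self.variants.iloc[idx],
            sim_params=self.sim_params,
        )

    def subset_samples(self, keep_samples: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.asarray([pos[s] for s in keep_samples])
        return GenotypeMatrix(
            self.dosages[idx], list(keep_samples), self.variants, sim_params=self.sim_params
        )


@dataclass
class ExpressionSet:
    """Gene expression counts for one condition.

    ``counts`` is genes x samples (raw integer counts); ``gene_annotation``
    is indexed by gene_id with ``chrom``, ``tss`` (1-based) and ``strand``
    columns; ``sample_covariates`` is samples x covariates (e.g. sex).
    """

    counts: pd.DataFrame
    condition: str
    gene_annotation: pd.DataFrame
    sample_covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        if not self.gene_annotation.index.name:
            self.gene_annotation = self.gene_annotation.copy()
            self.gene_annotation.index.name = "gene_id"

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def drop_samples(self, bad: Sequence[str]) -> "ExpressionSet":
        keep = [s for s in self.samples if s not in set(bad)]
        cov = self.sample_covariates
        return ExpressionSet(
            counts=self.counts[keep],
            condition=self.condition,
            gene_annotation=self.gene_annotation,
            sample_covariates=cov.loc[keep] if len(cov) else cov,
        )


@dataclass
class GwasSummary:
    """Per-variant marginal association summary statistics for one trait."""

    table: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, beta, se, p, n
    trait: str
    trait_type: str = "quant"  # {"quant", "cc"}

    def __post_init__(self) -> None:
        required = {"variant_id", "beta", "se", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS table lacks columns: {sorted(missing)}")
        if (self.table["se"] <= 0).any():
            raise ValueError("GWAS standard errors must be positive")
        if self.trait_type not in ("quant", "cc"):
            raise ValueError("trait_type must be 'quant' or 'cc'")


@dataclass
class GroundTruth:
    """Planted effects recorded by the generator for downstream validation."""

    true_eqtl_slopes: dict = field(default_factory=dict)  # (gene, variant, condition) -> slope
    true_de: dict = field(default_factory=dict)  # (gene, condition) -> (direction, log2fc)
    gwas_causal: dict = field(default_factory=dict)  # trait -> (variant, effect)
    outlier_samples: list = field(default_factory=list)

    def de_genes(self, condition: str) -> list[str]:
        return [g for (g, c) in self.true_de if c == condition]

    def to_json(self, path) -> None:
        payload = {
            "true_eqtl_slopes": {
                f"{g}|{v}|{c}": s for (g, v, c), s in sorted(self.true_eqtl_slopes.items())
            },
            "true_de": {
                f"{g}|{c}": {"direction": d, "log2fc": lfc}
                for (g, c), (d, lfc) in sorted(self.true_de.items())
            },
            "gwas_causal": {t: {"variant": v, "effect": e} for t, (v, e) in self.gwas_causal.items()},
            "outlier_samples": sorted(self.outlier_samples),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class QcReport:
    """Accounting for a filtering step: every input is either passed or
    attributed to the first filter it failed."""

    n_input: int
    n_pass: int
    removed: dict = field(default_factory=dict)  # filter name -> count
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pass + sum(self.removed.values()) != self.n_input:
            raise ValueError("QcReport accounting does not balance")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=str)


@dataclass
class BetaNullFit:
    """Beta(a, b) fitted to permutation minimum p-values for one gene."""

    a: float
    b: float
    n_perm_used: int
    empirical_pperm: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("beta shape parameters must be positive")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    H0 no association, H1/H2 trait-specific association, H3 two distinct
    causal variants, H4 one shared causal variant.
    """

    pp: np.ndarray  # length 5
    n_variants: int
    variant_ids: list
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    priors: tuple  # (p1, p2, p12)

    @property
    def pp_h0(self) -> float:
        return float(self.pp[0])

    @property
    def pp_h1(self) -> float:
        return float(self.pp[1])

    @property
    def pp_h2(self) -> float:
        return float(self.pp[2])

    @property
    def pp_h3(self) -> float:
        return float(self.pp[3])

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def h4_h3_ratio(self) -> float:
        return float(self.pp[4] / self.pp[3]) if self.pp[3] > 0 else float("inf")

    def as_dict(self) -> dict:
        return {
            "pp_h0": self.pp_h0,
            "pp_h1": self.pp_h1,
            "pp_h2": self.pp_h2,
            "pp_h3": self.pp_h3,
            "pp_h4": self.pp_h4,
            "pp_h4_h3_ratio": self.h4_h3_ratio,
            "n_variants": self.n_variants,
            "priors": {"p1": self.priors[0], "p2": self.priors[1], "p12": self.priors[2]},
        }


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)
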