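"""cis-eQTL mapping: expression preparation, cis pairing, nominal scan,
permutation/beta calibration and q-values."""
import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from e2qtl.datatypes import GenotypeMatrix
from e2qtl.eqtl import (
    PreparedExpression,
    cis_pairs,
    compute_qvalues,
    inverse_normal_transform,
    nominal_scan,
    permutation_pass,
    permutation_pass_all,
    prepare_expression,
)
from e2qtl.simulate import SimulationConfig, simulate_expression, simulate_genotypes


def _geno(dosages, pos=None):
    dosages = np.asarray(dosages, float)
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "chrom": "chr1",
            "pos": pos if pos is not None else 1000 + np.arange(m),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(dosages.shape[0])], variants)


def _prepared(y_matrix, samples=None, genes=None, n_cov=0):
    y = np.asarray(y_matrix, float)
    y = y - y.mean(axis=0)
    samples = samples or [f"s{i}" for i in range(y.shape[0])]
    genes = genes or [f"g{i}" for i in range(y.shape[1])]
    return PreparedExpression(
        data=pd.DataFrame(y, index=samples, columns=genes),
        n_covariates=n_cov,
        covariate_names=[],
    )


class TestInverseNormal:
    def test_five_values_map_to_expected_quantiles(self):
        vals = np.array([10.0, 2.0, 30.0, 4.0, 25.0])[:, None]
        out = inverse_normal_transform(vals, axis=0)[:, 0]
        expected_sorted = special.ndtri([0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(np.sort(out), expected_sorted, rtol=1e-12)

    def test_invariant_to_monotone_distortion(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (40, 3))
        np.testing.assert_allclose(
            inverse_normal_transform(x),
            inverse_normal_transform(np.exp(3 * x) + 7),
            rtol=1e-12,
        )

    def test_ties_get_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0])[:, None]
        out = inverse_normal_transform(x)[:, 0]
        assert out[0] == out[1]


class TestPrepareExpression:
    def _study(self):
        cfg = SimulationConfig(n_donors=60, n_variants=20, n_genes=40, seed=1,
                               conditions=("CTRL", "UVC"))
        g = simulate_genotypes(cfg)
        expr, _ = simulate_expression(g, cfg)
        return expr["CTRL"]

    def test_output_centered_per_gene(self):
        prep = prepare_expression(self._study(), n_expr_factors=3)
        assert np.abs(prep.data.mean(axis=0)).max() < 1e-10

    def test_covariate_equal_to_gene_residualizes_it_away(self):
        es = self._study()
        base = prepare_expression(es, n_expr_factors=0)
        gene = base.genes[0]
        cov = pd.DataFrame({"self": base.data[gene]}, index=base.samples)
        prep = prepare_expression(es, covariates=cov, n_expr_factors=0)
        assert np.abs(prep.data[gene]).max() < 1e-8

    def test_collinear_covariates_rejected(self):
        es = self._study()
        cov = pd.DataFrame({"ones": 1.0}, index=es.samples)
        with pytest.raises(ValueError, match="collinear"):
            prepare_expression(es, covariates=cov, n_expr_factors=0)


class TestCisPairs:
    def _genes(self, tss):
        return pd.DataFrame(
            {"chrom": "chr1", "tss": tss, "strand": "+"},
            index=pd.Index([f"g{i}" for i in range(len(tss))], name="gene_id"),
        )

    def test_window_boundary_inclusive(self):
        genes = self._genes([2_000_000])
        variants = pd.DataFrame(
            {"variant_id": ["a", "b"], "chrom": "chr1", "pos": [1_000_000, 999_999],
             "ref": "A", "alt": "G"}
        )
        pairs = cis_pairs(genes, variants, window=1_000_000)
        assert list(pairs["variant_id"]) == ["a"]
        assert pairs["distance"].iloc[0] == -1_000_000

    def test_other_chromosome_excluded(self):
        genes = self._genes([500])
        variants = pd.DataFrame(
            {"variant_id": ["a"], "chrom": "chr2", "pos": [600], "ref": "A", "alt": "G"}
        )
        assert len(cis_pairs(genes, variants)) == 0

    def test_gene_without_tss_skipped_with_warning(self):
        genes = self._genes([500.0, np.nan])
        variants = pd.DataFrame(
            {"variant_id": ["a"], "chrom": "chr1", "pos": [600], "ref": "A", "alt": "G"}
        )
        with pytest.warns(UserWarning, match="no TSS"):
            pairs = cis_pairs(genes, variants)
        assert set(pairs["gene_id"]) == {"g0"}


class TestNominalScan:
    def test_dosage_identical_to_expression(self):
        rng = np.random.default_rng(2)
        g_vec = rng.binomial(2, 0.4, 50).astype(float)
        geno = _geno(g_vec[:, None])
        prep = _prepared(g_vec[:, None], genes=["g0"])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"], "distance": [0]})
        res = nominal_scan(geno, prep, pairs, adjust_df=False)
        assert res["slope"].iloc[0] == pytest.approx(1.0)
        assert res["p_nominal"].iloc[0] < 1e-30

    def test_orthogonal_expression_gives_null(self):
        g_vec = np.array([0.0, 2.0] * 25)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 12 + [1.0, 1.0])
        y = y - y.mean()
        y = y - (y @ (g_vec - g_vec.mean())) / ((g_vec - g_vec.mean()) ** 2).sum() * (g_vec - g_vec.mean())
        geno = _geno(g_vec[:, None])
        prep = _prepared(y[:, None], genes=["g0"])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"], "distance": [0]})
        res = nominal_scan(geno, prep, pairs, adjust_df=False)
        assert res["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_nominal"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_planted_slope_within_three_se(self):
        hits = 0
        trials = 50
        for s in range(trials):
            rng = np.random.default_rng(100 + s)
            g_vec = rng.binomial(2, 0.3, 400).astype(float)
            y = 0.5 * g_vec + rng.normal(0, 1, 400)
            geno = _geno(g_vec[:, None])
            prep = _prepared((y - y.mean())[:, None], genes=["g0"])
            pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"], "distance": [0]})
            res = nominal_scan(geno, prep, pairs, adjust_df=False)
            lo = res["slope"].iloc[0] - 3 * res["se"].iloc[0]
            hi = res["slope"].iloc[0] + 3 * res["se"].iloc[0]
            hits += lo <= 0.5 <= hi
        assert hits / trials >= 0.9

    def test_zero_variance_variant_skipped(self):
        rng = np.random.default_rng(3)
        dosages = np.column_stack([np.full(20, 1.0), rng.binomial(2, 0.4, 20)])
        geno = _geno(dosages)
        prep = _prepared(rng.normal(0, 1, (20, 1)), genes=["g0"])
        pairs = pd.DataFrame({"gene_id": ["g0"] * 2, "variant_id": ["v0", "v1"],
                              "distance": [0, 10]})
        res = nominal_scan(geno, prep, pairs)
        assert list(res["variant_id"]) == ["v1"]


class TestPermutationPass:
    def _single_variant_case(self, seed, n=120):
        rng = np.random.default_rng(seed)
        g_vec = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(0, 1, n)
        geno = _geno(g_vec[:, None])
        prep = _prepared(y[:, None], genes=["g0"])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"], "distance": [0]})
        return geno, prep, pairs

    def test_single_variant_beta_p_tracks_nominal_p(self):
        """With one cis variant the permutation minimum is uniform, so the
        fitted beta is near Beta(1,1) and the adjusted p equals nominal."""
        for seed in range(5):
            geno, prep, pairs = self._single_variant_case(seed)
            rec, fit = permutation_pass(geno, prep, pairs, "g0",
                                        n_perm_min=10_000, n_perm_max=10_000, seed=seed)
            assert abs(rec["p_perm_beta"] - rec["p_nominal"]) < 0.02

    def test_orthogonal_gene_has_direct_p_one(self):
        g_vec = np.array([0.0, 2.0] * 30)
        gc = g_vec - g_vec.mean()
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 60)
        y = y - (y @ gc) / (gc @ gc) * gc  # exactly orthogonal: weakest possible
        geno = _geno(g_vec[:, None])
        prep = _prepared(y[:, None], genes=["g0"])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"], "distance": [0]})
        rec, fit = permutation_pass(geno, prep, pairs, "g0",
                                    n_perm_min=200, n_perm_max=200, seed=0)
        assert fit.empirical_pperm == pytest.approx(1.0)

    def test_small_n_perm_rejected(self):
        geno, prep, pairs = self._single_variant_case(0)
        with pytest.raises(ValueError, match="at least 100"):
            permutation_pass(geno, prep, pairs, "g0", n_perm_min=50)

    def test_deterministic_given_seed_and_independent_of_order(self):
        rng = np.random.default_rng(5)
        dosages = rng.binomial(2, 0.3, (100, 6)).astype(float)
        geno = _geno(dosages)
        y = rng.normal(0, 1, (100, 2))
        prep = _prepared(y, genes=["g0", "g1"])
        pairs = pd.DataFrame({
            "gene_id": ["g0"] * 3 + ["g1"] * 3,
            "variant_id": [f"v{i}" for i in range(6)],
            "distance": [0, 10, 20] * 2,
        })
        r1 = permutation_pass_all(geno, prep, pairs, n_perm_min=200, n_perm_max=200, seed=9)
        r2 = permutation_pass_all(geno, prep, pairs, n_perm_min=200, n_perm_max=200, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        # per-gene result identical when computed alone
        rec, _ = permutation_pass(geno, prep, pairs, "g1",
                                  n_perm_min=200, n_perm_max=200, seed=9)
        row = r1.set_index("gene_id").loc["g1"]
        assert rec["p_perm_beta"] == pytest.approx(row["p_perm_beta"], rel=1e-12)

    def test_top_variant_tie_breaks_by_distance(self):
        g_vec = np.array([0.0, 1.0, 2.0] * 20)
        dosages = np.column_stack([g_vec, g_vec])  # identical -> identical p
        geno = _geno(dosages)
        rng = np.random.default_rng(6)
        prep = _prepared(rng.normal(0, 1, (60, 1)), genes=["g0"])
        pairs = pd.DataFrame({"gene_id": ["g0"] * 2, "variant_id": ["v0", "v1"],
                              "distance": [10_000, 100]})
        rec, _ = permutation_pass(geno, prep, pairs, "g0",
                                  n_perm_min=100, n_perm_max=100, seed=0)
        assert rec["variant_id"] == "v1"


class TestQvalues:
    def test_stepup_enumeration_example(self):
        q = compute_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(compute_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        q = compute_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_storey_no_larger_than_bh(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.random(500)])
        q_bh = compute_qvalues(p, "bh")
        q_st = compute_qvalues(p, "storey")
        assert np.all(q_st <= q_bh + 1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([])
        with pytest.raises(ValueError):
            compute_qvalues([0.5, 1.5])
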