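"""TMM normalisation, moderated-t DE, DEG classification, ORA and GSEA."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from e2qtl.diffexpr import (
    bh_adjust,
    classify_degs,
    fit_de,
    gsea,
    normalize_counts,
    ora,
    ora_table,
    tmm_norm_factors,
)
from oracles import bh_stepup_oracle


def _counts(rows, cols, rng, mean=200.0):
    return pd.DataFrame(
        rng.poisson(mean, size=(rows, cols)),
        index=[f"g{i}" for i in range(rows)],
        columns=[f"s{j}" for j in range(cols)],
    )


class TestNormalization:
    def test_proportional_samples_have_identical_logcpm(self):
        rng = np.random.default_rng(0)
        s1 = rng.poisson(100, 500)
        counts = pd.DataFrame({"a": s1, "b": 2 * s1}, index=[f"g{i}" for i in range(500)])
        logcpm, factors = normalize_counts(counts)
        assert factors["a"] == pytest.approx(factors["b"], rel=1e-12)
        np.testing.assert_allclose(logcpm["a"], logcpm["b"], rtol=1e-12)

    def test_trimming_absorbs_single_spiked_gene(self):
        rng = np.random.default_rng(1)
        counts = _counts(1001, 6, rng)
        counts.iloc[0, :3] *= 8  # one strongly DE gene in half the samples
        factors = tmm_norm_factors(counts)
        assert np.all(np.abs(factors - 1.0) < 0.02)

    def test_all_zero_gene_is_constant_logcpm_row(self):
        rng = np.random.default_rng(2)
        counts = _counts(50, 4, rng)
        counts.iloc[0] = 0
        logcpm, _ = normalize_counts(counts, min_cpm=0.0, min_frac=0.0)
        row = logcpm.loc["g0"]
        # identical library sizes are not guaranteed, so allow tiny spread
        assert row.std() < 0.2

    def test_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            normalize_counts(counts)


class TestFitDe:
    def _design(self, n0, n1):
        return pd.DataFrame(
            {"condition": [0] * n0 + [1] * n1},
            index=[f"s{j}" for j in range(n0 + n1)],
        )

    def test_exact_logfc_with_zero_residual_variance(self):
        base = np.array([5.0, 5.0, 5.0, 6.5, 6.5, 6.5])
        logcpm = pd.DataFrame([base, base + 1.0], index=["g0", "g1"],
                              columns=[f"s{j}" for j in range(6)])
        res = fit_de(logcpm, self._design(3, 3))
        assert res.loc["g0", "log2fc"] == pytest.approx(1.5)
        assert res.loc["g1", "log2fc"] == pytest.approx(1.5)

    def test_logfc_equals_group_mean_difference(self):
        rng = np.random.default_rng(3)
        logcpm = pd.DataFrame(rng.normal(6, 1, (100, 12)),
                              index=[f"g{i}" for i in range(100)],
                              columns=[f"s{j}" for j in range(12)])
        res = fit_de(logcpm, self._design(6, 6))
        diff = logcpm.iloc[:, 6:].mean(axis=1) - logcpm.iloc[:, :6].mean(axis=1)
        np.testing.assert_allclose(res["log2fc"], diff, rtol=1e-10)

    def test_null_type_i_calibration(self):
        rng = np.random.default_rng(4)
        logcpm = pd.DataFrame(rng.normal(6, 1, (2000, 20)),
                              index=[f"g{i}" for i in range(2000)],
                              columns=[f"s{j}" for j in range(20)])
        res = fit_de(logcpm, self._design(10, 10))
        frac = (res["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_infinite_prior_df_equals_pooled_variance_t(self):
        rng = np.random.default_rng(5)
        logcpm = pd.DataFrame(rng.normal(6, 1, (300, 10)),
                              index=[f"g{i}" for i in range(300)],
                              columns=[f"s{j}" for j in range(10)])
        design = self._design(5, 5)
        res = fit_de(logcpm, design, prior_df=np.inf)
        # pooled common variance across genes, ordinary two-sample layout
        X = np.column_stack([np.ones(10), design["condition"]])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        resid = logcpm.to_numpy() @ (np.eye(10) - H)
        s2 = (resid**2).sum(axis=1) / (10 - 2)
        pooled = s2.mean()
        c = np.linalg.inv(X.T @ X)[1, 1]
        expected_t = res["log2fc"] / np.sqrt(pooled * c)
        np.testing.assert_allclose(res["t_moderated"], expected_t, rtol=1e-8)

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(6)
        logcpm = pd.DataFrame(rng.normal(6, 1, (10, 6)),
                              columns=[f"s{j}" for j in range(6)])
        design = self._design(3, 3)
        design["dup"] = design["condition"]
        with pytest.raises(ValueError):
            fit_de(logcpm, design)

    def test_p_adj_dominates_p(self):
        rng = np.random.default_rng(7)
        logcpm = pd.DataFrame(rng.normal(6, 1, (200, 8)),
                              columns=[f"s{j}" for j in range(8)])
        res = fit_de(logcpm, self._design(4, 4))
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert res["p_adj"].between(0, 1).all()


class TestBh:
    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


class TestClassifyDegs:
    def _tables(self):
        genes = ["g0", "g1", "g2", "g3"]
        def tab(lfc, padj):
            return pd.DataFrame({"log2fc": lfc, "p_adj": padj}, index=genes)
        return {
            "UVC": tab([2.0, -2.0, 1.5, 0.1], [0.01, 0.01, 0.04, 0.9]),
            "MMS": tab([0.2, -2.5, 2.2, 0.1], [0.50, 0.02, 0.20, 0.9]),
        }

    def test_labels_and_strict_boundaries(self):
        cls, summary = classify_degs(self._tables())
        assert cls.loc["g0", "label"] == "specific"  # UVC only
        assert cls.loc["g1", "label"] == "common"    # both stimuli
        # g2: log2fc exactly 1.5 in UVC (not > 1.5) and p_adj 0.2 in MMS
        assert cls.loc["g2", "label"] == "none"
        assert cls.loc["g3", "label"] == "none"
        assert summary.loc["UVC", "n_down"] == 1 and summary.loc["UVC", "n_up"] == 1

    def test_counts_invariant_to_gene_and_condition_order(self):
        tables = self._tables()
        cls1, s1 = classify_degs(tables)
        reordered = {
            c: t.iloc[::-1] for c, t in reversed(list(tables.items()))
        }
        cls2, s2 = classify_degs(reordered)
        pd.testing.assert_frame_equal(cls1.sort_index(), cls2.sort_index())
        pd.testing.assert_frame_equal(s1, s2)

    def test_all_rule_requires_every_stimulus(self):
        cls, _ = classify_degs(self._tables(), common_rule="all")
        assert cls.loc["g1", "label"] == "common"


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora(universe[:5], universe[:5], universe)
        from math import comb
        assert res["overlap"] == 5
        assert res["p"] == pytest.approx(1.0 / comb(20, 5), rel=1e-12)

    def test_overlap_at_expectation_is_nonsignificant(self):
        universe = [f"g{i}" for i in range(1000)]
        rng = np.random.default_rng(9)
        selected = list(rng.choice(universe, 100, replace=False))
        annot = universe[:100]
        res = ora(selected, annot, universe)
        if res["overlap"] <= 10:  # at or below expectation
            assert res["p"] >= 0.4

    def test_selected_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        res = ora(universe, universe[:7], universe)
        assert res["p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora(["a"], ["a"], [])

    def test_table_q_dominates_p(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {f"S{k}": universe[k * 10:(k + 1) * 10] for k in range(5)}
        out = ora_table(universe[:20], sets, universe)
        assert (out["q"] >= out["p"] - 1e-15).all()


class TestGsea:
    def _ranking(self, n=200, seed=10):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_top_of_ranking_scores_near_one(self):
        ranking = self._ranking()
        res = gsea(ranking, {"top": list(ranking.index[:10])}, n_perm=200, seed=0)
        assert res.loc["top", "es"] > 0.9
        assert res.loc["top", "p"] < 0.05

    def test_whole_ranking_set_has_null_running_sum(self):
        ranking = self._ranking(50)
        res = gsea(ranking, {"all": list(ranking.index)}, n_perm=50, seed=0)
        # a set covering the entire ranking has no misses: the running sum
        # cannot deviate from zero
        assert res.loc["all", "es"] == pytest.approx(0.0, abs=1e-12)

    def test_random_sets_rarely_reach_large_nes(self):
        ranking = self._ranking(300, seed=11)
        rng = np.random.default_rng(12)
        sets = {
            f"R{k}": list(rng.choice(ranking.index, 20, replace=False))
            for k in range(40)
        }
        res = gsea(ranking, sets, n_perm=200, seed=1)
        assert (res["nes"].abs() < 2).mean() >= 0.9

    def test_zero_overlap_set_skipped_with_warning(self):
        ranking = self._ranking(50)
        with pytest.warns(UserWarning, match="no overlap"):
            res = gsea(ranking, {"alien": ["zz1", "zz2"]}, n_perm=50, seed=0)
        assert len(res) == 0

    def test_duplicate_genes_rejected(self):
        s = pd.Series([1.0, 0.5], index=["a", "a"])
        with pytest.raises(ValueError):
            gsea(s, {"S": ["a"]})
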