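"""Ward clustering, correlation-matrix PCA, factorial GLM and LSD post-hoc."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from repquant.repertoire import (
    bonferroni_alpha,
    factorial_glm,
    lsd_posthoc,
    pca_retain,
    ward_cluster,
)

from oracles import balanced_two_way_anova, brute_force_ward, linkage_to_merges


class TestWardCluster:
    def test_identical_rows_merge_at_height_zero(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        d = ward_cluster(X)
        assert d.linkage[0, 2] == 0.0

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(pd.DataFrame([[1.0, 2.0]]))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_ess_oracle(self, seed):
        """Merge sequence and ESS-increase heights equal the from-scratch
        greedy agglomeration that recomputes within-cluster SSE per pair."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        X = rng.normal(size=(n, int(rng.integers(1, 5))))
        d = ward_cluster(pd.DataFrame(X))
        got = linkage_to_merges(d.linkage, n)
        exp_merges, exp_heights = brute_force_ward(X)
        for (ga, gb), (ea, eb) in zip(got, exp_merges):
            assert {ga, gb} == {ea, eb}
        np.testing.assert_allclose(d.heights, exp_heights, rtol=1e-9, atol=1e-12)

    def test_heights_match_scipy_ward(self):
        """Independent cross-check: scipy's Ward heights are sqrt(2 * ESS
        increase), so h_scipy^2 / 2 must equal our squared-Euclidean heights."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(12, 6))
        d = ward_cluster(pd.DataFrame(X))
        Z = sch.linkage(X, method="ward")
        np.testing.assert_allclose(d.heights, Z[:, 2] ** 2 / 2, rtol=1e-9)
        assert linkage_to_merges(d.linkage, 12) == linkage_to_merges(Z, 12)

    def test_permutation_leaves_topology_unchanged(self, small_matrix):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_matrix.values.shape[0])
        shuffled = small_matrix.values.iloc[perm]
        cut_a = ward_cluster(small_matrix.values).cut(3)
        cut_b = ward_cluster(shuffled).cut(3).reindex(cut_a.index)
        # same partition up to label renaming
        table = pd.crosstab(cut_a, cut_b)
        assert (table.gt(0).sum(axis=1) == 1).all()
        assert (table.gt(0).sum(axis=0) == 1).all()

    def test_newick_export_is_parseable(self, small_matrix):
        dendropy = pytest.importorskip("dendropy")
        d = ward_cluster(small_matrix)
        tree = dendropy.Tree.get(data=d.to_newick(), schema="newick")
        assert len(tree.leaf_nodes()) == small_matrix.n_samples


class TestPcaRetain:
    def test_two_perfectly_correlated_variables(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        comps = pca_retain(df)
        np.testing.assert_allclose(comps.eigenvalues, [2.0, 0.0], atol=1e-12)
        assert comps.retained == 1

    def test_eigenvalue_spectrum_invariants(self, small_matrix):
        comps = pca_retain(small_matrix)
        ev = comps.eigenvalues
        assert (np.diff(ev) <= 1e-9).all()
        assert abs(ev.sum() - small_matrix.values.shape[1]) < 1e-6
        assert (ev[: comps.retained] > 1.0).all()

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 4)))
        comps = pca_retain(df, criterion=0.0)  # keep every positive component
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        eigvec = comps.loadings.to_numpy() / np.sqrt(comps.eigenvalues[: comps.loadings.shape[1]])
        np.testing.assert_allclose(comps.scores.to_numpy() @ eigvec.T, Z, atol=1e-8)

    def test_independent_variables_have_near_unit_eigenvalues(self):
        """With independent unit-variance variables the correlation spectrum
        concentrates at 1, and Kaiser retention shrinks as n grows (sampling
        noise above 1 fades)."""
        rng = np.random.default_rng(9)
        small = pca_retain(pd.DataFrame(rng.normal(size=(40, 10))))
        large = pca_retain(pd.DataFrame(rng.normal(size=(5000, 10))))
        assert np.all(np.abs(large.eigenvalues - 1.0) < 0.2)
        # the sampling-noise excess above 1 shrinks as n grows
        assert large.eigenvalues[0] < small.eigenvalues[0]

    def test_zero_variance_columns_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            comps = pca_retain(df)
        assert comps.dropped_columns == ["const"]
        with pytest.raises(ValueError):
            pca_retain(pd.DataFrame({"c1": np.ones(5), "c2": np.ones(5)}))


class TestFactorialGlm:
    def test_balanced_two_by_two_matches_closed_form(self):
        rng = np.random.default_rng(8)
        status = np.repeat(["GF", "colonised"], 8)
        tissue = np.tile(np.repeat(["spleen", "proximal_jejunum"], 4), 2)
        y = (
            rng.normal(size=16)
            + 0.8 * (status == "colonised")
            + 1.5 * (tissue == "spleen")
        )
        scores = pd.DataFrame({"PC1": y})
        meta = pd.DataFrame({"status": status, "tissue": tissue})
        glm = factorial_glm(scores, meta, n_components=1)
        oracle = balanced_two_way_anova(y, status, tissue)
        row = glm.table.loc["PC1"]
        assert abs(row["status_F"] - oracle["A"][0]) < 1e-10
        assert abs(row["status_p"] - oracle["A"][1]) < 1e-10
        assert abs(row["tissue_F"] - oracle["B"][0]) < 1e-10
        assert abs(row["interaction_p"] - oracle["AB"][1]) < 1e-10

    def test_single_level_factor_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({"PC1": rng.normal(size=8)})
        meta = pd.DataFrame(
            {"status": ["GF"] * 8, "tissue": ["spleen"] * 4 + ["proximal_jejunum"] * 4}
        )
        with pytest.warns(UserWarning, match="single level"):
            glm = factorial_glm(scores, meta, n_components=1)
        assert np.isnan(glm.table.loc["PC1", "status_p"])
        assert np.isfinite(glm.table.loc["PC1", "tissue_p"])

    def test_pvalues_invariant_to_sample_order(self, small_matrix):
        comps = pca_retain(small_matrix)
        glm_a = factorial_glm(comps, small_matrix.meta)
        rng = np.random.default_rng(4)
        perm = rng.permutation(small_matrix.n_samples)
        scores_p = comps.scores.iloc[perm]
        glm_b = factorial_glm(scores_p, small_matrix.meta.iloc[perm])
        pd.testing.assert_frame_equal(glm_a.table, glm_b.table, atol=1e-10, rtol=0)

    def test_null_type_one_error_calibrated(self):
        """Under pure noise each term rejects at ~alpha: 500 replicates of a
        2x3 design, nominal alpha 0.05, binomial 95% tolerance band."""
        rng = np.random.default_rng(123)
        status = np.repeat(["GF", "colonised"], 12)
        tissue = np.tile(
            np.repeat(["spleen", "proximal_jejunum", "distal_jejunum"], 4), 2
        )
        meta = pd.DataFrame({"status": status, "tissue": tissue})
        hits = {"status_p": 0, "tissue_p": 0, "interaction_p": 0}
        n_rep = 500
        for _ in range(n_rep):
            scores = pd.DataFrame({"PC1": rng.normal(size=24)})
            table = factorial_glm(scores, meta, n_components=1).table
            for k in hits:
                hits[k] += table.iloc[0][k] < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        for k, h in hits.items():
            assert abs(h / n_rep - 0.05) < band + 0.01, (k, h / n_rep)


class TestBonferroni:
    @pytest.mark.parametrize(
        "family,n,expected",
        [(0.05, 5, 0.01), (0.05, 1, 0.05), (0.05, 15, 0.05 / 15)],
    )
    def test_arithmetic(self, family, n, expected):
        assert bonferroni_alpha(family, n) == pytest.approx(expected, abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 5)


class TestLsdPosthoc:
    def test_pairwise_t_matches_scipy_for_two_groups(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=10)
        out = lsd_posthoc(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10)
        t, p = stats.ttest_ind(a, b)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_all_pairs_reported(self):
        out = lsd_posthoc(list(range(9)), ["a", "b", "c"] * 3)
        assert len(out) == 3
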