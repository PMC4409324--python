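"""AMMI/GGE decomposition, imputation and dendrograms: reconstruction,
sum-of-squares oracles, standardization invariance and merge-order checks."""

import numpy as np
import pandas as pd
import pytest

from rootgxe.gxe import (AMMI, GGE, LowRankImputer, ammi_decompose,
                         cluster_dendrogram, gge_decompose, impute_missing,
                         ss_partition_percent)
from rootgxe.phenotype import ls_means
from rootgxe.simulate import SimulationConfig, gen_phenotype


def _additive(ng=5, ne=4, mu=50.0):
    g = np.arange(ng) - (ng - 1) / 2
    e = 2.0 * (np.arange(ne) - (ne - 1) / 2)
    Y = mu + g[:, None] + e[None, :]
    return pd.DataFrame(Y, index=[f"g{i}" for i in range(ng)],
                        columns=[f"e{j}" for j in range(ne)])


class TestImputation:
    def test_complete_matrix_is_fixed_point(self, small_matrix):
        imp = LowRankImputer()
        out = imp.fit_transform(small_matrix)
        pd.testing.assert_frame_equal(out, small_matrix)
        assert imp.converged_ and imp.n_iter_ == 0

    def test_additive_missing_cell_filled_exactly(self):
        M = _additive()
        holed = M.copy()
        holed.iloc[1, 2] = np.nan
        out = impute_missing(holed, rank=1)
        assert out.iloc[1, 2] == pytest.approx(M.iloc[1, 2], abs=1e-8)
        # observed cells untouched
        mask = ~holed.isna()
        pd.testing.assert_frame_equal(out[mask], holed[mask])

    def test_rank1_interaction_recovered(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=8)
        M = _additive(10, 8) + 3.0 * pd.DataFrame(
            np.outer(a - a.mean(), b - b.mean()),
            index=[f"g{i}" for i in range(10)],
            columns=[f"e{j}" for j in range(8)])
        holed = M.copy()
        cells = [(1, 2), (3, 5), (7, 0), (9, 6)]  # ~5% of 80 cells
        for i, j in cells:
            holed.iloc[i, j] = np.nan
        out = impute_missing(holed, rank=1, tol=1e-12, max_iter=2000)
        for i, j in cells:
            assert out.iloc[i, j] == pytest.approx(M.iloc[i, j], abs=1e-6)

    def test_sparse_row_rejected(self):
        M = _additive()
        M.iloc[0, :3] = np.nan
        with pytest.raises(ValueError, match="2 observed"):
            impute_missing(M)


class TestAMMI:
    def test_full_reconstruction(self, small_matrix):
        d = ammi_decompose(small_matrix)
        pd.testing.assert_frame_equal(d.reconstruct(), small_matrix,
                                      atol=1e-8, check_exact=False)

    def test_mean_polish_residual_is_double_centered(self, small_matrix):
        fit = AMMI().fit(small_matrix)
        R = (small_matrix.to_numpy() - fit.grand_mean_
             - fit.genotype_effects_.to_numpy()[:, None]
             - fit.environment_effects_.to_numpy()[None, :])
        assert np.allclose(R.sum(axis=0), 0, atol=1e-8)
        assert np.allclose(R.sum(axis=1), 0, atol=1e-8)

    def test_ss_matches_brute_force_anova(self, rng):
        Y = rng.normal(10, 2, size=(5, 4))
        M = pd.DataFrame(Y)
        d = ammi_decompose(M)
        grand = Y.mean()
        ss_g = sum(4 * (Y[i].mean() - grand) ** 2 for i in range(5))
        ss_e = sum(5 * (Y[:, j].mean() - grand) ** 2 for j in range(4))
        ss_ge = sum((Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
                    for i in range(5) for j in range(4))
        assert d.ss["ss_G"] == pytest.approx(ss_g, rel=1e-10)
        assert d.ss["ss_E"] == pytest.approx(ss_e, rel=1e-10)
        assert d.ss["ss_GxE"] == pytest.approx(ss_ge, rel=1e-10)
        assert d.ss["ss_total"] == pytest.approx(ss_g + ss_e + ss_ge, rel=1e-10)
        assert (d.singular_values ** 2).sum() == pytest.approx(ss_ge, rel=1e-8)
        assert d.df == {"df_G": 4, "df_E": 3, "df_GxE": 12}

    def test_additive_matrix_has_no_interaction(self):
        with pytest.warns(UserWarning, match="non-degenerate"):
            d = ammi_decompose(_additive())
        assert d.ss["ss_GxE"] == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(d.singular_values, 0, atol=1e-10)

    def test_rank1_interaction_loads_on_pc1(self):
        M = _additive(6, 5)
        a = np.array([1, -1, 2, -2, 0.5, -0.5])
        b = np.array([1, 2, -1, -2, 0])
        M += np.outer(a - a.mean(), b - b.mean())
        d = ammi_decompose(M)
        assert d.pc_percent[0] == pytest.approx(100.0, abs=1e-8)

    def test_score_sign_convention(self, small_matrix):
        d = ammi_decompose(small_matrix)
        for k in range(d.genotype_scores.shape[1]):
            col = d.genotype_scores.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] >= 0

    def test_scores_orthonormal(self, small_matrix):
        d = ammi_decompose(small_matrix)
        A = d.genotype_scores.to_numpy()
        C = d.environment_scores.to_numpy()
        assert np.allclose(A.T @ A, np.eye(A.shape[1]), atol=1e-8)
        assert np.allclose(C.T @ C, np.eye(C.shape[1]), atol=1e-8)
        assert np.all(np.diff(d.singular_values) <= 1e-12)


class TestGGE:
    def test_scores_equal_svd_of_standardized_matrix(self, rng):
        Y = rng.normal(size=(4, 3))
        M = pd.DataFrame(Y)
        d = gge_decompose(M)
        Z = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        assert np.allclose(d.singular_values, s[:2], atol=1e-10)
        assert np.allclose(np.abs(d.genotype_scores.to_numpy()),
                           np.abs(U[:, :2]), atol=1e-8)

    def test_invariant_to_environment_affine_rescaling(self, small_matrix):
        d1 = gge_decompose(small_matrix)
        scaled = small_matrix.copy()
        scaled.iloc[:, 1] = scaled.iloc[:, 1] * 10.0 + 7.0
        d2 = gge_decompose(scaled)
        pd.testing.assert_frame_equal(d1.genotype_scores, d2.genotype_scores,
                                      atol=1e-10, check_exact=False)
        pd.testing.assert_frame_equal(d1.environment_scores,
                                      d2.environment_scores,
                                      atol=1e-10, check_exact=False)

    def test_consistent_rankings_put_environments_on_one_side(self):
        # same genotype ordering everywhere -> environment scores share PC1 sign
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        M = pd.DataFrame(np.column_stack([g, 2 * g + 1, 0.5 * g - 2, g + 3]))
        d = gge_decompose(M)
        pc1 = d.environment_scores["PC1"].to_numpy()
        assert np.all(pc1 > 0) or np.all(pc1 < 0)
        assert d.pc_percent[0] == pytest.approx(100.0, abs=1e-6)

    def test_zero_variance_environment_dropped(self, small_matrix):
        M = small_matrix.copy()
        M.iloc[:, 3] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            d = gge_decompose(M)
        assert "e3" not in d.environment_scores.index


def test_ss_partition_sums_to_100(small_matrix):
    parts = ss_partition_percent(ammi_decompose(small_matrix))
    assert parts["pct_G"] + parts["pct_E"] + parts["pct_GxE"] == \
        pytest.approx(100.0, abs=0.1)
    assert sum(parts[f"pct_PC{k}"] for k in range(1, 4)) <= 100.0 + 1e-6


def test_variance_fraction_recovery_over_replicates():
    """Mean absolute error of recovered (pct_G, pct_E, pct_GxE) vs truth over
    20 simulation replicates at 4 blocks stays under 3 percentage points."""
    target = {"G": 0.10, "E": 0.60, "GxE": 0.20, "error": 0.10}
    errs = []
    for rep in range(20):
        cfg = SimulationConfig(seed=100 + rep, variance_fractions=target,
                               n_blocks_per_env=4, missing_rate=0.0)
        obs, truth = gen_phenotype(cfg)
        parts = ss_partition_percent(ammi_decompose(ls_means(obs, cfg.trait)))
        tv = truth.realized_variance_fractions
        denom = tv["G"] + tv["E"] + tv["GxE"]
        for comp in ("G", "E", "GxE"):
            errs.append(abs(parts[f"pct_{comp}"] - 100 * tv[comp] / denom))
    assert np.mean(errs) < 3.0


class TestDendrogram:
    def test_identical_rows_merge_first_at_zero(self):
        M = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0],
                          [3.0, 8.0, 0.0]], index=list("abcd"))
        tree = cluster_dendrogram(M, "genotypes")
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(tree.linkage[0, :2]) == [0, 1]

    def test_points_on_a_line_merge_nearest_first(self):
        M = pd.DataFrame({"x": [0.0, 1.0, 10.0], "y": [0.0, 1.0, 10.0]},
                         index=list("abc"))
        tree = cluster_dendrogram(M, "genotypes")
        assert sorted(tree.linkage[0, :2]) == [0, 1]  # (0,1) before 10 joins

    def test_merge_order_matches_naive_average_linkage(self, rng):
        M = pd.DataFrame(rng.normal(size=(5, 4)),
                         index=[f"g{i}" for i in range(5)])
        tree = cluster_dendrogram(M, "genotypes")

        # O(n^3) oracle on the same standardized profiles
        Z = (M - M.mean()) / M.std(ddof=1)
        clusters = {i: [i] for i in range(5)}
        dmat = np.sqrt(((Z.to_numpy()[:, None, :] -
                         Z.to_numpy()[None, :, :]) ** 2).sum(-1))
        heights = []
        next_id = 5
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    d = np.mean([dmat[i, j] for i in clusters[a]
                                 for j in clusters[b]])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        np.testing.assert_allclose(tree.merge_heights(), heights, rtol=1e-10)

    def test_newick_roundtrip_preserves_leaves(self, small_matrix):
        import dendropy
        tree = cluster_dendrogram(small_matrix, "environments")
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert leaves == set(small_matrix.columns)

    def test_pair_without_shared_cells_rejected(self):
        M = pd.DataFrame([[1.0, np.nan, 2.0], [np.nan, 3.0, np.nan],
                          [1.0, 2.0, 3.0]], index=list("abc"))
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            cluster_dendrogram(M, "genotypes")
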