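"""Co-expression network construction: adjacency, soft threshold, TOM,
clustering, tree cut, eigengenes, merging."""

import numpy as np
import pandas as pd
import pytest

from hepanet.netbuild import (UNASSIGNED, adjacency_matrix, average_linkage,
                              dynamic_tree_cut, merge_close_modules,
                              module_eigengene, pick_soft_threshold,
                              tom_similarity)


def _expr(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"{prefix}{i:03d}" for i in range(values.shape[0])],
                        columns=[f"S{i:02d}" for i in range(values.shape[1])])


def _planted_expr(rng, block_sizes, strength, n_background, n_samples=20):
    """Blocks of genes sharing a latent factor plus iid noise."""
    rows = []
    for size in block_sizes:
        f = rng.normal(0, 1, n_samples)
        noise = rng.normal(0, 1, (size, n_samples))
        rows.append(strength * f[None, :] + np.sqrt(1 - strength ** 2) * noise)
    if n_background:
        rows.append(rng.normal(0, 1, (n_background, n_samples)))
    return _expr(np.vstack(rows))


class TestAdjacency:
    def test_perfect_anticorrelation_is_unsigned(self):
        x = np.arange(6.0)
        expr = _expr([x, -x])
        a = adjacency_matrix(expr, beta=6)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_beta_one_is_absolute_correlation(self, rng):
        expr = _expr(rng.normal(0, 1, (2, 10)))
        a = adjacency_matrix(expr, beta=1)
        r = np.corrcoef(expr.to_numpy())[0, 1]
        assert a.iloc[0, 1] == pytest.approx(abs(r))

    def test_matches_elementwise_oracle(self, rng):
        expr = _expr(rng.normal(0, 1, (30, 12)))
        a = adjacency_matrix(expr, beta=18).to_numpy()
        r = np.corrcoef(expr.to_numpy())
        oracle = np.abs(r) ** 18
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(a, oracle, atol=1e-12)

    def test_constant_gene_dropped_with_warning(self, rng):
        values = rng.normal(0, 1, (5, 8))
        values[2] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            a = adjacency_matrix(_expr(values), beta=6)
        assert a.shape == (4, 4) and "G002" not in a.index

    def test_mean_connectivity_nonincreasing_in_beta(self, rng):
        expr = _expr(rng.normal(0, 1, (40, 15)))
        means = []
        for beta in (1, 2, 4, 8, 16):
            a = adjacency_matrix(expr, beta=beta).to_numpy()
            np.fill_diagonal(a, 0.0)
            means.append(a.sum(1).mean())
        assert all(m1 >= m2 - 1e-12 for m1, m2 in zip(means, means[1:]))


class TestSoftThreshold:
    def test_modular_blocks_give_positive_signed_r2(self, rng):
        """Well-separated blocks: degree distribution slope is negative, so
        the signed index is positive wherever defined."""
        expr = _planted_expr(rng, [30, 30], 0.95, 60)
        scan = pick_soft_threshold(expr, candidate_powers=range(2, 13))
        valid = scan.table.dropna(subset=["r2_signed"])
        assert (valid["r2_signed"] > 0).mean() > 0.7

    def test_chooses_smallest_power_meeting_target(self, rng):
        expr = _planted_expr(rng, [50, 50], 0.9, 100)
        scan = pick_soft_threshold(expr, candidate_powers=range(1, 21),
                                   target_r2=0.85)
        valid = scan.table.dropna(subset=["r2_signed"])
        meeting = valid[valid["r2_signed"] >= 0.85]
        if not meeting.empty:
            assert scan.chosen == meeting["power"].iloc[0]
        else:
            assert scan.chosen == valid.loc[valid["r2_signed"].idxmax(), "power"]

    def test_needs_two_candidates(self, rng):
        expr = _planted_expr(rng, [10], 0.9, 10)
        with pytest.raises(ValueError):
            pick_soft_threshold(expr, candidate_powers=[6])


def tom_oracle(A: np.ndarray) -> np.ndarray:
    """O(n^3) triple-loop topological overlap."""
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + A0[i, j]) / (min(k[i], k[j]) + 1.0 - A0[i, j])
    return tom


class TestTOM:
    def test_complete_graph(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom.to_numpy(), 1.0)

    def test_empty_graph(self):
        a = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        tom = tom_similarity(a).to_numpy()
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.uniform(0, 1, (20, 20))
        A = (x + x.T) / 2
        np.fill_diagonal(A, 1.0)
        adf = pd.DataFrame(A, index=[f"g{i}" for i in range(20)],
                           columns=[f"g{i}" for i in range(20)])
        np.testing.assert_allclose(tom_similarity(adf).to_numpy(),
                                   tom_oracle(A), atol=1e-12)

    def test_asymmetry_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        adf = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(adf)

    def test_bounds_on_random_inputs(self, rng):
        """TOM stays within [0, 1] over many random adjacency matrices."""
        for _ in range(200):
            n = rng.integers(3, 12)
            x = rng.uniform(0, 1, (n, n))
            A = (x + x.T) / 2
            np.fill_diagonal(A, 1.0)
            adf = pd.DataFrame(A)
            tom = tom_similarity(adf).to_numpy()
            assert tom.min() >= -1e-12 and tom.max() <= 1.0 + 1e-12


def upgma_oracle(D: np.ndarray):
    """Naive UPGMA returning sorted merge heights."""
    clusters = {i: [i] for i in range(D.shape[0])}
    dist = {(i, j): D[i, j] for i in range(D.shape[0])
            for j in range(i + 1, D.shape[0])}
    heights = []
    next_id = D.shape[0]
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k in list(clusters):
            d = np.mean([D[a, b] for a in merged for b in clusters[k]])
            dist[(min(k, next_id), max(k, next_id))] = d
        clusters[next_id] = merged
        next_id += 1
    return np.sort(np.asarray(heights))


class TestAverageLinkage:
    def test_two_blocks_merge_last(self, rng):
        D = np.full((6, 6), 0.9)
        D[:3, :3] = 0.1
        D[3:, 3:] = 0.1
        np.fill_diagonal(D, 0.0)
        Z = average_linkage(pd.DataFrame(D))
        assert Z[-1, 2] == pytest.approx(0.9)
        assert (Z[:-1, 2] <= 0.1 + 1e-12).all()

    def test_hand_computed_three_points(self):
        D = np.array([[0.0, 0.1, 0.5],
                      [0.1, 0.0, 0.5],
                      [0.5, 0.5, 0.0]])
        Z = average_linkage(pd.DataFrame(D))
        np.testing.assert_allclose(Z[:, 2], [0.1, 0.5])

    def test_matches_naive_upgma_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            x = rng.uniform(0.05, 1.0, (n, n))
            D = (x + x.T) / 2
            np.fill_diagonal(D, 0.0)
            Z = average_linkage(pd.DataFrame(D))
            np.testing.assert_allclose(np.sort(Z[:, 2]), upgma_oracle(D),
                                       atol=1e-10)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(pd.DataFrame(D))


class TestTreeCut:
    def test_planted_blocks_recovered(self, rng):
        """Two 50-gene blocks at strength 0.9 plus 100 background genes:
        exactly 2 modules, assignment matching truth (ARI >= 0.9)."""
        from sklearn.metrics import adjusted_rand_score

        expr = _planted_expr(rng, [50, 50], 0.9, 100)
        adj = adjacency_matrix(expr, beta=12)
        diss = 1.0 - tom_similarity(adj)
        np.fill_diagonal(diss.values, 0.0)
        labels = dynamic_tree_cut(average_linkage(diss), adj.index,
                                  min_module_size=30)
        truth = [0] * 50 + [1] * 50 + [2] * 100
        found = labels[labels != UNASSIGNED]
        assert labels.nunique() == 3  # two modules + grey
        ari = adjusted_rand_score(truth, pd.factorize(labels)[0])
        assert ari >= 0.9
        assert len(found) >= 90

    def test_min_size_larger_than_clusters_gives_all_grey(self, rng):
        expr = _planted_expr(rng, [20], 0.9, 20)
        adj = adjacency_matrix(expr, beta=6)
        diss = 1.0 - tom_similarity(adj)
        np.fill_diagonal(diss.values, 0.0)
        labels = dynamic_tree_cut(average_linkage(diss), adj.index,
                                  min_module_size=100)
        assert (labels == UNASSIGNED).all()

    def test_block_below_min_size_is_grey(self, rng):
        """A 29-gene block with min_module_size=30 stays unassigned."""
        expr = _planted_expr(rng, [29], 0.95, 60)
        adj = adjacency_matrix(expr, beta=6)
        diss = 1.0 - tom_similarity(adj)
        np.fill_diagonal(diss.values, 0.0)
        labels = dynamic_tree_cut(average_linkage(diss), adj.index,
                                  min_module_size=30,
                                  cut_height=0.6 * diss.to_numpy().max())
        assert (labels.iloc[:29] == UNASSIGNED).all()

    def test_labels_stable_under_gene_reordering(self, rng):
        expr = _planted_expr(rng, [40, 35], 0.9, 50)
        perm = rng.permutation(len(expr))
        shuffled = expr.iloc[perm]

        def pipeline(e):
            adj = adjacency_matrix(e, beta=6)
            diss = 1.0 - tom_similarity(adj)
            np.fill_diagonal(diss.values, 0.0)
            return dynamic_tree_cut(average_linkage(diss), adj.index,
                                    min_module_size=30)

        l1, l2 = pipeline(expr), pipeline(shuffled)
        pd.testing.assert_series_equal(l1.sort_index(), l2.sort_index())

    def test_invalid_cut_height(self, rng):
        expr = _planted_expr(rng, [10], 0.9, 10)
        adj = adjacency_matrix(expr, beta=6)
        diss = 1.0 - tom_similarity(adj)
        np.fill_diagonal(diss.values, 0.0)
        Z = average_linkage(diss)
        with pytest.raises(ValueError, match="cut height"):
            dynamic_tree_cut(Z, adj.index, cut_height=2 * Z[:, 2].max())


class TestEigengene:
    def test_single_gene_module(self, rng):
        expr = _expr(rng.normal(0, 1, (1, 10)))
        me = module_eigengene(expr, pd.Series(["blue"], index=expr.index))
        e = me.eigengenes.loc["blue"].to_numpy()
        z = expr.iloc[0].to_numpy()
        z = (z - z.mean()) / z.std(ddof=1)
        corr = np.corrcoef(e, z)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        assert me.variance_explained["blue"] == pytest.approx(1.0)

    def test_rank_one_limit(self, rng):
        v = rng.normal(0, 1, 12)
        block = np.outer(rng.uniform(0.5, 2.0, 20), v)
        block += rng.normal(0, 0.01, block.shape)
        expr = _expr(block)
        me = module_eigengene(expr, pd.Series("m", index=expr.index))
        r = np.corrcoef(me.eigengenes.loc["m"], v)[0, 1]
        assert abs(r) >= 0.99

    def test_matches_svd_oracle(self, rng):
        expr = _expr(rng.normal(0, 1, (15, 10)))
        labels = pd.Series("m", index=expr.index)
        me = module_eigengene(expr, labels)
        Z = expr.to_numpy()
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, ddof=1, keepdims=True)
        w = np.linalg.eigvalsh(Z @ Z.T)
        assert me.variance_explained["m"] == pytest.approx(w[-1] / w.sum(),
                                                           abs=1e-10)

    def test_unit_norm_and_sign_convention(self, rng):
        expr = _planted_expr(rng, [20], 0.9, 0)
        me = module_eigengene(expr, pd.Series("m", index=expr.index))
        e = me.eigengenes.loc["m"].to_numpy()
        assert np.linalg.norm(e) == pytest.approx(1.0)
        Z = expr.to_numpy()
        Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, ddof=1, keepdims=True)
        assert np.corrcoef(e, Z.mean(0))[0, 1] >= 0


class TestMergeModules:
    @staticmethod
    def _correlated_blocks(rng, r_between, sizes=(30, 30), n=30):
        f1 = rng.normal(0, 1, n)
        f2 = r_between * f1 + np.sqrt(1 - r_between ** 2) * rng.normal(0, 1, n)
        rows, labels = [], []
        for f, size, name in zip((f1, f2), sizes, ("turquoise", "blue")):
            rows.append(0.95 * f[None, :]
                        + 0.3 * rng.normal(0, 1, (size, n)))
            labels += [name] * size
        expr = _expr(np.vstack(rows))
        return expr, pd.Series(labels, index=expr.index)

    def test_highly_correlated_modules_merge(self, rng):
        expr, labels = self._correlated_blocks(rng, 0.97)
        merged, me = merge_close_modules(expr, labels, cut_height=0.15)
        assert merged.nunique() == 1
        assert len(me.modules) == 1

    def test_distinct_modules_unchanged(self, rng):
        expr, labels = self._correlated_blocks(rng, 0.3)
        merged, me = merge_close_modules(expr, labels, cut_height=0.15)
        pd.testing.assert_series_equal(merged, labels, check_names=False)

    def test_merge_reaches_fixed_point(self, rng):
        """After merging, no remaining pair of eigengenes exceeds the
        merge threshold."""
        n = 40
        f1 = rng.normal(0, 1, n)
        f2 = 0.9 * f1 + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        f3 = 0.9 * f2 + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        rows, labels = [], []
        for f, name in zip((f1, f2, f3), ("a", "b", "c")):
            rows.append(0.97 * f[None, :] + 0.2 * rng.normal(0, 1, (25, n)))
            labels += [name] * 25
        expr = _expr(np.vstack(rows))
        merged, me = merge_close_modules(expr, pd.Series(labels, index=expr.index),
                                         cut_height=0.15)
        E = me.eigengenes.to_numpy()
        if len(me.modules) > 1:
            C = np.corrcoef(E)
            off = C[~np.eye(len(C), dtype=bool)]
            assert off.max() <= 0.85 + 1e-9
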