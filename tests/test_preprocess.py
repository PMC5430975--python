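"""Normalization, filtering, batch adjustment and MDS."""

import numpy as np
import pandas as pd
import pytest

from hepanet.datasets import ExprMatrix, NormalizationFactors
from hepanet.preprocess import (compute_cpm, compute_rpkm, filter_low_expression,
                                library_sizes, log2_transform, mds_top_sd,
                                remove_batch_effect, tmm_factors)
from .conftest import make_dataset


# ---------------------------------------------------------------- CPM / RPKM

class TestCPM:
    def test_unit_library(self, small_dataset):
        """A count of 100 in an effective library of 1e6 gives CPM 100."""
        ds = small_dataset
        ds.counts.iloc[0, 0] = 100
        factors = NormalizationFactors(
            library_sizes=pd.Series(1e6, index=ds.sample_ids),
            tmm_factors=pd.Series(1.0, index=ds.sample_ids))
        cpm = compute_cpm(ds, factors)
        assert cpm.values.iloc[0, 0] == pytest.approx(100.0)

    def test_all_zero_gene(self, small_dataset):
        small_dataset.counts.iloc[3, :] = 0
        cpm = compute_cpm(small_dataset)
        assert (cpm.values.iloc[3] == 0).all()

    def test_matches_formula_oracle(self, rng):
        ds = make_dataset(rng, n_genes=50, n_samples=6)
        factors = tmm_factors(ds)
        cpm = compute_cpm(ds, factors)
        eff = (ds.counts.sum(0) * factors.tmm_factors).to_numpy()
        expected = ds.counts.to_numpy() / eff[None, :] * 1e6
        np.testing.assert_allclose(cpm.values.to_numpy(), expected, rtol=1e-12)

    def test_columns_sum_to_million_with_unit_factors(self, small_dataset):
        cpm = compute_cpm(small_dataset)
        np.testing.assert_allclose(cpm.values.sum(0), 1e6, rtol=1e-9)


class TestRPKM:
    def test_definitional(self, small_dataset):
        ds = small_dataset
        ds.counts.iloc[0, 0] = 10
        ds.gene_lengths.iloc[0] = 1000
        factors = NormalizationFactors(
            library_sizes=pd.Series(1e7, index=ds.sample_ids),
            tmm_factors=pd.Series(1.0, index=ds.sample_ids))
        rpkm = compute_rpkm(ds, factors)
        assert rpkm.values.iloc[0, 0] == pytest.approx(1.0)

    def test_length_proportionality_and_cpm_ratio(self, rng):
        ds = make_dataset(rng)
        factors = tmm_factors(ds)
        rpkm = compute_rpkm(ds, factors).values
        cpm = compute_cpm(ds, factors).values
        # RPKM/CPM per gene is the constant 1e3/length in every sample
        ratio = rpkm / cpm.replace(0, np.nan)
        expected = 1e3 / ds.gene_lengths
        for col in ratio.columns:
            ok = ratio[col].notna()
            np.testing.assert_allclose(ratio.loc[ok, col],
                                       expected[ok], rtol=1e-12)

    def test_missing_length_names_gene(self, small_dataset):
        small_dataset.gene_lengths.iloc[2] = np.nan
        with pytest.raises(ValueError, match="G002"):
            compute_rpkm(small_dataset)


# -------------------------------------------------------------------- filter

class TestFilter:
    def _expr(self, values, n_samples):
        cols = [f"S{i}" for i in range(n_samples)]
        df = pd.DataFrame(values, columns=cols)
        df.index = [f"G{i}" for i in range(len(df))]
        return ExprMatrix(values=df, scale="CPM")

    def test_boundary_kept_at_exactly_min_samples(self):
        """'Above 1 in at least 5 samples': 5 samples at CPM 2 is kept."""
        expr = self._expr([[2, 2, 2, 2, 2, 0, 0, 0]], 8)
        assert list(filter_low_expression(expr)) == ["G0"]

    def test_strict_inequality_on_cpm(self):
        """CPM exactly 1 everywhere is not 'above 1' and is dropped."""
        expr = self._expr([[1.0] * 8], 8)
        assert list(filter_low_expression(expr)) == []

    def test_matches_row_scan_oracle(self, rng):
        values = rng.uniform(0, 3, size=(40, 9))
        expr = self._expr(values, 9)
        kept = set(filter_low_expression(expr, min_cpm=1, min_samples=5))
        oracle = {f"G{i}" for i, row in enumerate(values)
                  if sum(v > 1 for v in row) >= 5}
        assert kept == oracle

    def test_idempotent(self, rng):
        values = rng.uniform(0, 3, size=(30, 8))
        expr = self._expr(values, 8)
        kept = filter_low_expression(expr)
        again = filter_low_expression(
            ExprMatrix(values=expr.values.loc[kept], scale="CPM"))
        assert list(kept) == list(again)

    def test_min_samples_exceeding_count_errors(self, rng):
        expr = self._expr(rng.uniform(0, 3, size=(5, 4)), 4)
        with pytest.raises(ValueError, match="min_samples"):
            filter_low_expression(expr, min_samples=5)


# ----------------------------------------------------------------------- TMM

def tmm_oracle(counts: np.ndarray, ref_idx: int) -> np.ndarray:
    """Independent trim-and-weight TMM recipe (plain loops)."""
    N = counts.sum(axis=0).astype(float)
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        M, A, w = [], [], []
        for g in range(counts.shape[0]):
            x, xr = counts[g, j], counts[g, ref_idx]
            if x > 0 and xr > 0:
                p, pr = x / N[j], xr / N[ref_idx]
                M.append(np.log2(p / pr))
                A.append(0.5 * np.log2(p * pr))
                w.append((N[j] - x) / (N[j] * x)
                         + (N[ref_idx] - xr) / (N[ref_idx] * xr))
        M, A, w = map(np.asarray, (M, A, w))
        n = len(M)
        order_m = np.argsort(M, kind="stable")
        rank_m = np.empty(n); rank_m[order_m] = np.arange(1, n + 1)
        order_a = np.argsort(A, kind="stable")
        rank_a = np.empty(n); rank_a[order_a] = np.arange(1, n + 1)
        keep = ((rank_m >= np.floor(n * 0.3) + 1) & (rank_m <= n - np.floor(n * 0.3))
                & (rank_a >= np.floor(n * 0.05) + 1) & (rank_a <= n - np.floor(n * 0.05)))
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        ds = make_dataset(rng, n_genes=60, n_samples=4)
        col = ds.counts.iloc[:, 0]
        for c in ds.counts.columns:
            ds.counts[c] = col
        f = tmm_factors(ds)
        np.testing.assert_allclose(f.tmm_factors, 1.0, atol=1e-12)

    def test_global_doubling_is_absorbed_by_library_size(self, rng):
        ds = make_dataset(rng, n_genes=80, n_samples=4)
        ds.counts.iloc[:, 1] = ds.counts.iloc[:, 0] * 2
        f = tmm_factors(ds, reference_sample=ds.sample_ids[0])
        assert f.tmm_factors.iloc[1] == pytest.approx(
            f.tmm_factors.iloc[0], rel=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        """10% of genes 4-fold up in one sample: factors equal the
        independently coded trim-and-weight recipe."""
        ds = make_dataset(rng, n_genes=200, n_samples=6)
        up = rng.choice(200, size=20, replace=False)
        ds.counts.iloc[up, 2] *= 4
        ref = 0
        f = tmm_factors(ds, reference_sample=ds.sample_ids[ref])
        oracle = tmm_oracle(ds.counts.to_numpy(), ref)
        np.testing.assert_allclose(f.tmm_factors.to_numpy(), oracle, rtol=1e-10)

    def test_geometric_mean_is_one(self, rng):
        ds = make_dataset(rng, n_genes=100, n_samples=5)
        f = tmm_factors(ds)
        assert np.exp(np.mean(np.log(f.tmm_factors))) == pytest.approx(1.0, abs=1e-8)

    def test_disjoint_support_errors(self, rng):
        ds = make_dataset(rng, n_genes=10, n_samples=3)
        ds.counts.iloc[:5, 0] = 0
        ds.counts.iloc[5:, 1] = 0
        ds.counts.iloc[:, 2] = 1
        with pytest.raises(ValueError, match="no expressed genes"):
            tmm_factors(ds, reference_sample=ds.sample_ids[0])


# ------------------------------------------------------------- log transform

@pytest.mark.parametrize("value,expected", [(0, 0), (1, 1), (7, 3)])
def test_log2_prior_one(value, expected):
    df = pd.DataFrame([[float(value)]], index=["g"], columns=["s"])
    out = log2_transform(ExprMatrix(values=df, scale="CPM"))
    assert out.values.iloc[0, 0] == pytest.approx(expected)
    assert out.scale == "log2CPM"


def test_log2_rejects_negative():
    df = pd.DataFrame([[-0.5]], index=["g"], columns=["s"])
    with pytest.raises(ValueError):
        log2_transform(ExprMatrix(values=df, scale="CPM"))


# ------------------------------------------------------------ batch removal

def _log_expr(values, batches):
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(len(values))],
                      columns=[f"S{i}" for i in range(len(batches))])
    batch = pd.Series(batches, index=df.columns)
    return ExprMatrix(values=df, scale="log2RPKM"), batch


class TestRemoveBatch:
    def test_single_batch_is_identity(self, rng):
        expr, batch = _log_expr(rng.normal(5, 1, (10, 6)), [1] * 6)
        out = remove_batch_effect(expr, batch)
        np.testing.assert_allclose(out.values, expr.values)

    def test_exact_offset_recovery(self, rng):
        base = rng.normal(5, 1, size=(20, 1)) * np.ones((20, 8))
        offsets = np.where(np.arange(8) < 4, 1.7, 0.0)[None, :]
        expr, batch = _log_expr(base + offsets, [1] * 4 + [2] * 4)
        out = remove_batch_effect(expr, batch)
        v = out.values.to_numpy()
        np.testing.assert_allclose(v[:, :4].mean(1), v[:, 4:].mean(1), atol=1e-10)
        # sum-to-zero coding keeps each gene's observed grand mean
        np.testing.assert_allclose(v.mean(1), (base + offsets).mean(1), atol=1e-10)

    def test_matches_per_gene_ols_oracle(self, rng):
        n = 12
        batches = [1, 2, 3] * 4
        expr, batch = _log_expr(rng.normal(5, 1, (15, n)), batches)
        out = remove_batch_effect(expr, batch)
        # oracle: per-gene lstsq on [1 | sum-to-zero batch], subtract batch part
        Xb = np.zeros((n, 2))
        codes = np.asarray(batches) - 1
        for j in range(2):
            Xb[:, j] = (codes == j).astype(float) - (codes == 2)
        X = np.column_stack([np.ones(n), Xb])
        for g in range(15):
            y = expr.values.iloc[g].to_numpy()
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(out.values.iloc[g], y - Xb @ coef[1:],
                                       atol=1e-8)

    def test_idempotent(self, rng):
        expr, batch = _log_expr(rng.normal(5, 1, (15, 9)), [1, 2, 3] * 3)
        once = remove_batch_effect(expr, batch)
        twice = remove_batch_effect(once, batch)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-8)

    def test_confounded_preserve_errors(self, rng):
        expr, batch = _log_expr(rng.normal(5, 1, (5, 6)), [1, 1, 1, 2, 2, 2])
        preserve = pd.DataFrame({"intercept": 1.0,
                                 "group": [1, 1, 1, 0, 0, 0]},
                                index=expr.sample_ids, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            remove_batch_effect(expr, batch, preserve)


# ------------------------------------------------------------------------ MDS

class TestMDS:
    def test_duplicated_sample_coincides(self, rng):
        values = rng.normal(5, 2, size=(50, 5))
        values[:, 4] = values[:, 0]
        df = pd.DataFrame(values, index=[f"G{i}" for i in range(50)],
                          columns=[f"S{i}" for i in range(5)])
        coords = mds_top_sd(ExprMatrix(values=df, scale="log2CPM"), n_top=50)
        np.testing.assert_allclose(coords.loc["S0"], coords.loc["S4"], atol=1e-8)

    def test_equilateral_triangle_isometry(self):
        # three samples at mutual Euclidean distance d
        d = 2.0
        values = np.array([[1.0, 0.0, 0.0],
                           [0.0, 1.0, 0.0],
                           [0.0, 0.0, 1.0]]) * d / np.sqrt(2)
        df = pd.DataFrame(values.T, index=["g1", "g2", "g3"],
                          columns=["a", "b", "c"])
        coords = mds_top_sd(ExprMatrix(values=df, scale="log2CPM"), n_top=3)
        pts = coords.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(d, abs=1e-8)

    def test_matches_skbio_pcoa(self, rng):
        """Coordinates agree (up to axis sign) with an independent classical
        MDS implementation."""
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.ordination import pcoa

        values = rng.normal(0, 1, size=(80, 7))
        df = pd.DataFrame(values, index=[f"G{i}" for i in range(80)],
                          columns=[f"S{i}" for i in range(7)])
        expr = ExprMatrix(values=df, scale="log2CPM")
        coords = mds_top_sd(expr, n_top=80, n_dims=2)
        ref = pcoa(squareform(pdist(values.T)), number_of_dimensions=2)
        for k in range(2):
            a = coords.iloc[:, k].to_numpy()
            b = ref.samples.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_too_many_dims_errors(self, rng):
        values = rng.normal(0, 1, size=(20, 4))
        df = pd.DataFrame(values, index=[f"G{i}" for i in range(20)],
                          columns=[f"S{i}" for i in range(4)])
        with pytest.raises(ValueError, match="n_dims"):
            mds_top_sd(ExprMatrix(values=df, scale="log2CPM"), n_dims=4)
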