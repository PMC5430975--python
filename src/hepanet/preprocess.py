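"""Expression filtering, CPM/TMM/RPKM normalization, batch removal and MDS.

The normalization dialect follows the standard RNA-seq toolchain: counts
per million over TMM-effective library sizes, a CPM > 1 in >= 5 samples
expression filter applied jointly across all samples, RPKM for
length-aware cross-gene comparisons, log2(x + 1) transforms, per-gene
least-squares batch adjustment with sum-to-zero batch coding, and
classical (Torgerson) metric MDS on the 500 genes with the largest
across-sample standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datasets import CountDataset, ExprMatrix, NormalizationFactors

__all__ = [
    "library_sizes",
    "tmm_factors",
    "compute_cpm",
    "compute_rpkm",
    "filter_low_expression",
    "log2_transform",
    "remove_batch_effect",
    "mds_top_sd",
]


def library_sizes(dataset: CountDataset) -> pd.Series:
    sizes = dataset.counts.sum(axis=0).astype(float)
    if (sizes == 0).any():
        bad = sizes.index[sizes == 0][0]
        raise ValueError(f"zero library size for sample {bad}")
    return sizes


def tmm_factors(
    dataset: CountDataset,
    reference_sample: str | None = None,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors.

    Per sample, gene-wise log ratios M = log2((x/N)/(xr/Nr)) and abundances
    A = 0.5*log2((x/N)*(xr/Nr)) are computed over genes expressed in both
    the sample and the reference; the top/bottom 30% by M and 5% by A are
    trimmed; the factor is 2 to the inverse-binomial-variance-weighted mean
    of the surviving M values.  Factors are rescaled to geometric mean 1.

    The reference defaults to the sample whose upper-quartile CPM is
    closest to the mean upper quartile across samples.
    """
    counts = dataset.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    sizes = library_sizes(dataset)
    N = sizes.to_numpy()
    cpm = counts / N[None, :] * 1e6

    if reference_sample is None:
        expressed = counts.sum(axis=1) > 0
        uq = np.percentile(cpm[expressed], 75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = int(dataset.sample_ids.get_loc(reference_sample))

    xr = counts[:, ref_idx]
    Nr = N[ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        x = counts[:, j]
        both = (x > 0) & (xr > 0)
        if not both.any():
            raise ValueError(
                f"sample {dataset.sample_ids[j]} shares no expressed genes "
                f"with reference {dataset.sample_ids[ref_idx]}")
        p = x[both] / N[j]
        pr = xr[both] / Nr
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        # delta-method variance of M under binomial sampling
        w = (N[j] - x[both]) / (N[j] * x[both]) + (Nr - xr[both]) / (Nr * xr[both])

        n = M.size
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n - np.floor(n * abundance_trim)
        rank_m = pd.Series(M).rank(method="first").to_numpy()
        rank_a = pd.Series(A).rank(method="first").to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones_like(keep, dtype=bool)
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        library_sizes=sizes,
        tmm_factors=pd.Series(factors, index=dataset.sample_ids, name="tmm"),
    )


def compute_cpm(dataset: CountDataset, factors: NormalizationFactors | None = None) -> ExprMatrix:
    """Counts per million over (TMM-effective) library sizes."""
    if factors is None:
        factors = NormalizationFactors.unit(library_sizes(dataset))
    eff = factors.effective_sizes
    if (eff <= 0).any():
        bad = eff.index[eff <= 0][0]
        raise ValueError(f"nonpositive effective library size for sample {bad}")
    values = dataset.counts / eff * 1e6
    return ExprMatrix(values=values, scale="CPM", provenance=["cpm"])


def compute_rpkm(dataset: CountDataset, factors: NormalizationFactors | None = None) -> ExprMatrix:
    """Reads per kilobase per million mapped, over effective library sizes."""
    if factors is None:
        factors = NormalizationFactors.unit(library_sizes(dataset))
    missing = dataset.counts.index.difference(dataset.gene_lengths.dropna().index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]}")
    eff = factors.effective_sizes
    values = dataset.counts.mul(1e9).div(eff, axis=1).div(dataset.gene_lengths, axis=0)
    return ExprMatrix(values=values, scale="RPKM", provenance=["rpkm"])


def filter_low_expression(cpm: ExprMatrix, min_cpm: float = 1.0, min_samples: int = 5) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in at least ``min_samples``
    samples, evaluated jointly across every sample in the matrix."""
    if cpm.scale != "CPM":
        raise ValueError(f"expected a CPM-scale matrix, got {cpm.scale!r}")
    if min_samples > cpm.values.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {cpm.values.shape[1]}")
    keep = (cpm.values > min_cpm).sum(axis=1) >= min_samples
    return cpm.values.index[keep]


def log2_transform(expr: ExprMatrix, prior: float = 1.0) -> ExprMatrix:
    if (expr.values.to_numpy() < 0).any():
        raise ValueError("negative expression values cannot be log transformed")
    values = np.log2(expr.values + prior)
    return expr.with_values(values, scale=f"log2{expr.scale}", step=f"log2(+{prior:g})")


def _sum_to_zero_batch(batch: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(batch))
    if len(levels) < 2:
        return np.empty((len(batch), 0)), levels
    X = np.zeros((len(batch), len(levels) - 1))
    codes = batch.map({b: i for i, b in enumerate(levels)}).to_numpy()
    for j in range(len(levels) - 1):
        X[:, j] = (codes == j).astype(float)
    X[codes == len(levels) - 1, :] = -1.0
    return X, levels


def remove_batch_effect(
    expr: ExprMatrix,
    batch: pd.Series,
    preserve: pd.DataFrame | None = None,
) -> ExprMatrix:
    """Subtract the fitted batch component from a log-scale matrix.

    Per gene, ordinary least squares is fit on [preserve design | batch
    indicators in sum-to-zero coding] and only the batch part of the fit is
    removed, so biological group means are untouched and adjusted values
    stay centered on the grand mean.  ``preserve`` defaults to an
    intercept.
    """
    if "log2" not in expr.scale:
        raise ValueError("batch adjustment expects a log-scale matrix")
    batch = batch.loc[expr.sample_ids]
    counts_per_batch = batch.value_counts()
    if (counts_per_batch < 1).any():  # pragma: no cover - defensive
        raise ValueError("empty batch level")

    Xb, levels = _sum_to_zero_batch(batch)
    if Xb.shape[1] == 0:
        return expr.with_values(expr.values.copy(), expr.scale, "remove_batch(single batch)")

    if preserve is None:
        Xp = np.ones((len(batch), 1))
    else:
        Xp = np.asarray(preserve.loc[expr.sample_ids], dtype=float)
        if Xp.ndim == 1:
            Xp = Xp[:, None]
    X = np.hstack([Xp, Xb])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "batch is collinear with a preserved design column; the batch "
            "component is not estimable")

    Y = expr.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    batch_part = Xb @ coef[Xp.shape[1]:, :]
    adjusted = pd.DataFrame(Y - batch_part.T, index=expr.gene_ids, columns=expr.sample_ids)
    scale = expr.scale if expr.scale.startswith("batch_adjusted") else f"batch_adjusted_{expr.scale}"
    return expr.with_values(adjusted, scale, f"remove_batch(levels={levels})")


def mds_top_sd(expr: ExprMatrix, n_top: int = 500, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of samples.

    Distances are Euclidean over the ``n_top`` genes with the largest
    across-sample standard deviation; coordinates come from the
    eigendecomposition of the double-centered squared-distance matrix.
    Returns one row per sample with ``dim1..dimk`` coordinates plus the
    variance explained per axis in ``df.attrs["variance_explained"]``.
    """
    n_samples = expr.values.shape[1]
    if n_dims > n_samples - 1:
        raise ValueError(f"n_dims={n_dims} exceeds sample count - 1 ({n_samples - 1})")
    if n_top > expr.values.shape[0]:
        n_top = expr.values.shape[0]

    sd = expr.values.std(axis=1, ddof=1)
    top = sd.sort_values(ascending=False, kind="mergesort").index[:n_top]
    M = expr.values.loc[top].to_numpy(dtype=float)

    diff = M[:, :, None] - M[:, None, :]
    D2 = np.einsum("gij,gij->ij", diff, diff)
    J = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.maximum(eigval, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coords = eigvec[:, :n_dims] * np.sqrt(pos[:n_dims])[None, :]
    out = pd.DataFrame(coords, index=expr.sample_ids,
                       columns=[f"dim{i + 1}" for i in range(n_dims)])
    total = pos.sum()
    out.attrs["variance_explained"] = (pos[:n_dims] / total if total > 0
                                       else np.zeros(n_dims))
    return out
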