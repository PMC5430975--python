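"""Negative-binomial differential transcript analysis.

Counts are modeled as NB with a log link, offsets equal to the log
TMM-effective library sizes, and a fixed per-gene dispersion.  Dispersions
are estimated by a method-of-moments fit on Pearson residuals of a
Poisson fit with a degrees-of-freedom inflation (n / (n - p)), then shrunk
on the log scale toward a trimmed-mean common value.  Contrasts are tested
with a likelihood-ratio test: the null model is the full design projected
onto the contrast's null space, the statistic is referred to chi-square
with 1 df, and p-values are corrected by Benjamini-Hochberg.

The breed/sex interaction contrasts follow the study design: within each
drug, (Treated_A - Untreated_A) - (Treated_B - Untreated_B) for each
pair of breeds A, B, and the analogous male-vs-female contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "DesignMatrix",
    "DispersionEstimates",
    "NBFit",
    "build_design",
    "treatment_contrast",
    "interaction_contrast",
    "estimate_dispersions",
    "fit_nb_glm",
    "lrt_contrast",
    "bh_fdr",
]

_DISP_FLOOR = 1e-6
_ETA_CLIP = 30.0


@dataclass
class DesignMatrix:
    """Labeled design matrix aligned with a count matrix's samples."""

    matrix: pd.DataFrame  # samples x columns

    @property
    def X(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def columns(self) -> pd.Index:
        return self.matrix.columns

    def contrast(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.columns))
        for name, w in weights.items():
            if name not in self.columns:
                raise ValueError(f"design has no column {name!r} "
                                 f"(available: {list(self.columns)})")
            c[self.columns.get_loc(name)] = w
        return c


@dataclass
class DispersionEstimates:
    common: float
    tagwise: pd.Series
    shrinkage_weight: float


@dataclass
class NBFit:
    coef: pd.DataFrame        # genes x design columns
    log_likelihood: pd.Series
    converged: pd.Series
    design: DesignMatrix


def _drop_aliased(df: pd.DataFrame) -> pd.DataFrame:
    """Greedily keep columns that increase the rank (original order)."""
    keep: list[str] = []
    X = np.empty((len(df), 0))
    for col in df.columns:
        cand = np.column_stack([X, df[col].to_numpy(float)])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            keep.append(col)
            X = cand
    return df[keep]


def _batch_columns(samples: pd.DataFrame) -> pd.DataFrame:
    levels = sorted(pd.unique(samples["batch"]))
    out = pd.DataFrame(index=samples.index)
    if len(levels) < 2:
        return out
    codes = samples["batch"].map({b: i for i, b in enumerate(levels)})
    for j, level in enumerate(levels[:-1]):
        col = (codes == j).astype(float)
        col[codes == len(levels) - 1] = -1.0
        out[f"batch{level}"] = col
    return out


def build_design(samples: pd.DataFrame, scheme: str = "overall") -> DesignMatrix:
    """Construct the model matrix for one drug arm.

    ``overall``: intercept + treated indicator + sum-to-zero batch terms.
    ``by_breed`` / ``by_sex``: cell-means coding with one column per
    nonempty (group x treated/untreated) cell, plus batch terms.
    Aliased columns (e.g. a batch entirely confounded with a cell) are
    dropped in order, so the returned matrix is always full column rank.
    """
    for col in ("treatment", "batch"):
        if col not in samples.columns or samples[col].isna().any():
            raise ValueError(f"every sample needs a {col} label")
    treated = samples["treatment"] != "UNT"

    if scheme == "overall":
        design = pd.DataFrame({"intercept": 1.0, "treated": treated.astype(float)},
                              index=samples.index)
    elif scheme in ("by_breed", "by_sex"):
        group_col = "breed" if scheme == "by_breed" else "sex"
        if group_col not in samples.columns:
            raise ValueError(f"samples lack a {group_col} column")
        design = pd.DataFrame(index=samples.index)
        for group in sorted(pd.unique(samples[group_col])):
            for status, mask in (("T", treated), ("U", ~treated)):
                cell = (samples[group_col] == group) & mask
                if cell.any():
                    design[f"{status}_{group}"] = cell.astype(float)
    else:
        raise ValueError(f"unknown design scheme {scheme!r}")

    design = pd.concat([design, _batch_columns(samples)], axis=1)
    return DesignMatrix(_drop_aliased(design))


def treatment_contrast(design: DesignMatrix) -> np.ndarray:
    """Treated vs untreated in the overall design."""
    return design.contrast({"treated": 1.0})


def interaction_contrast(design: DesignMatrix, group_a: str, group_b: str) -> np.ndarray:
    """(Treated_A - Untreated_A) - (Treated_B - Untreated_B) in a
    cell-means design; errors list any empty (missing) cell."""
    needed = [f"T_{group_a}", f"U_{group_a}", f"T_{group_b}", f"U_{group_b}"]
    missing = [c for c in needed if c not in design.columns]
    if missing:
        raise ValueError(f"empty design cells for contrast: {missing}")
    return design.contrast({f"T_{group_a}": 1.0, f"U_{group_a}": -1.0,
                            f"T_{group_b}": -1.0, f"U_{group_b}": 1.0})


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across genes)

def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood with fixed dispersion (phi -> 0 is Poisson)."""
    phi = np.asarray(phi, dtype=float)
    ll = np.empty(Y.shape[0])
    poisson = phi < 1e-10
    if poisson.any():
        y, m = Y[poisson], mu[poisson]
        ll[poisson] = np.sum(y * np.log(m) - m - gammaln(y + 1.0), axis=1)
    nb = ~poisson
    if nb.any():
        y, m = Y[nb], mu[nb]
        r = (1.0 / phi[nb])[:, None]
        ll[nb] = np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + m)) + y * np.log(m / (r + m) + 1e-300),
            axis=1,
        )
    return ll


def _irls(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
          tol: float = 1e-8, max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for the NB log-link GLM with fixed dispersions.

    Returns (coef (G, p), log-likelihood (G,), converged (G,)).
    """
    G, n = Y.shape
    p = X.shape[1]
    off = np.broadcast_to(offset, (G, n))
    mu0 = np.maximum(Y, 0.5)
    beta = np.linalg.lstsq(X, (np.log(mu0) - off).T, rcond=None)[0].T
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p)[None] * 1e-10
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + phi[:, None] * mu)
        z = eta - off + (Y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + eye
        XtWz = np.einsum("ni,gn->gi", X, W * z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(new - beta).max(axis=1)
        beta = new
        converged |= step < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
    ll = _nb_loglik(Y, np.exp(eta), phi)
    return beta, ll, converged


def estimate_dispersions(
    counts: pd.DataFrame,
    design: DesignMatrix,
    offsets: pd.Series | np.ndarray,
    shrinkage_weight: float = 0.7,
    trim: float = 0.1,
) -> DispersionEstimates:
    """Moment dispersions from Pearson residuals of a Poisson fit.

    Per gene, ``Var(y) = mu + phi mu^2`` is solved from the Pearson
    chi-square of a Poisson IRLS fit, inflated by n/(n - p) for the
    degrees of freedom spent on the mean model.  The common dispersion is
    the trimmed mean; tagwise values shrink toward it on the log scale
    with a fixed weight.  Everything is clamped to >= 1e-6.
    """
    Y = counts.to_numpy(dtype=float)
    X = design.X
    n, p = X.shape
    if n - p < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    off = np.asarray(offsets, dtype=float)
    beta, _, _ = _irls(Y, X, off, np.zeros(Y.shape[0]))
    mu = np.exp(np.clip(beta @ X.T + np.broadcast_to(off, Y.shape), -_ETA_CLIP, _ETA_CLIP))
    X2 = ((Y - mu) ** 2 / mu).sum(axis=1)
    denom = mu.sum(axis=1) * (n - p) / n
    raw = (X2 - (n - p)) / denom
    raw *= n / (n - p)  # df inflation: moment estimator is biased low at small n
    raw = np.maximum(raw, _DISP_FLOOR)

    from scipy.stats import trim_mean
    common = float(max(trim_mean(raw, trim), _DISP_FLOOR))
    w = shrinkage_weight
    tagwise = np.exp(w * np.log(common) + (1.0 - w) * np.log(raw))
    tagwise = np.maximum(tagwise, _DISP_FLOOR)
    return DispersionEstimates(
        common=common,
        tagwise=pd.Series(tagwise, index=counts.index, name="dispersion"),
        shrinkage_weight=w,
    )


def fit_nb_glm(
    counts: pd.DataFrame,
    design: DesignMatrix,
    offsets: pd.Series | np.ndarray,
    dispersions: DispersionEstimates | pd.Series | np.ndarray,
) -> NBFit:
    """Fit the NB GLM per gene (IRLS, fixed dispersion).

    Non-convergence after 50 iterations is flagged per gene, not fatal.
    """
    Y = counts.to_numpy(dtype=float)
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    phi = (dispersions.tagwise if isinstance(dispersions, DispersionEstimates)
           else pd.Series(np.asarray(dispersions), index=counts.index))
    phi = phi.loc[counts.index].to_numpy(dtype=float)
    off = np.asarray(offsets, dtype=float)
    beta, ll, conv = _irls(Y, X, off, phi)
    return NBFit(
        coef=pd.DataFrame(beta, index=counts.index, columns=design.columns),
        log_likelihood=pd.Series(ll, index=counts.index),
        converged=pd.Series(conv, index=counts.index),
        design=design,
    )


def lrt_contrast(
    fit: NBFit,
    counts: pd.DataFrame,
    offsets: pd.Series | np.ndarray,
    dispersions: DispersionEstimates | pd.Series | np.ndarray,
    contrast: np.ndarray,
    label: str = "contrast",
) -> pd.DataFrame:
    """Likelihood-ratio test of a single-df contrast.

    The null model reparameterizes the design onto the null space of the
    contrast; the statistic 2*(ll_full - ll_null) is referred to
    chi-square(1).  log2FC = (contrast . coef) / ln 2.
    """
    contrast = np.asarray(contrast, dtype=float)
    X = fit.design.X
    if contrast.shape != (X.shape[1],):
        raise ValueError("contrast length does not match design columns")
    phi = (dispersions.tagwise if isinstance(dispersions, DispersionEstimates)
           else pd.Series(np.asarray(dispersions), index=counts.index))
    phi = phi.loc[counts.index].to_numpy(dtype=float)
    off = np.asarray(offsets, dtype=float)
    log2fc = (fit.coef.to_numpy() @ contrast) / np.log(2.0)

    if np.allclose(contrast, 0.0):
        stat = np.zeros(len(counts))
        pval = np.ones(len(counts))
    else:
        # check estimability: contrast must lie in the design's row space
        proj = X.T @ np.linalg.pinv(X.T) @ contrast
        if not np.allclose(proj, contrast, atol=1e-8):
            raise ValueError("contrast is not estimable in this design")
        K = scipy.linalg.null_space(contrast[None, :])
        Y = counts.to_numpy(dtype=float)
        _, ll_null, _ = _irls(Y, X @ K, off, phi)
        stat = np.maximum(2.0 * (fit.log_likelihood.to_numpy() - ll_null), 0.0)
        pval = chi2.sf(stat, df=1)

    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "contrast": label,
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pval,
            "fdr": bh_fdr(pval),
        }
    )
    return out.reset_index(drop=True)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH correction")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
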