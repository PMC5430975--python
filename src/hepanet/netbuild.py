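"""Unsigned weighted co-expression network construction.

Adjacency is |Pearson r|^beta between gene expression profiles; beta is
chosen by the scale-free topology criterion; genes are clustered by
average linkage on the topological-overlap dissimilarity; modules are
branches of the dendrogram cut at a fixed height with a minimum size, are
named by size rank from the conventional color palette ("grey" reserved
for unassigned genes), and modules whose eigengenes correlate above
1 - merge_cut_height are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "SoftThresholdScan",
    "ModuleEigengenes",
    "adjacency_matrix",
    "pick_soft_threshold",
    "tom_similarity",
    "average_linkage",
    "dynamic_tree_cut",
    "module_eigengene",
    "merge_close_modules",
]

# Size-rank module names, in the conventional WGCNA-style palette order;
# "grey" is reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

UNASSIGNED = "grey"


def _module_name(rank: int) -> str:
    return MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"


def _drop_constant(expr: pd.DataFrame, strict: bool) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        if strict:
            raise ValueError(f"constant gene(s): {list(expr.index[constant][:5])}")
        warnings.warn(f"dropping {int(constant.sum())} constant gene(s)")
        expr = expr.loc[~constant]
    return expr


def adjacency_matrix(expr: pd.DataFrame, beta: float, strict: bool = False) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with unit diagonal.

    ``expr`` is genes x samples (>= 3 samples).  Constant genes are dropped
    with a warning (or raise in strict mode).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a co-expression network")
    expr = _drop_constant(expr, strict)
    r = np.corrcoef(expr.to_numpy(dtype=float))
    r = np.clip(r, -1.0, 1.0)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


@dataclass
class SoftThresholdScan:
    """Per-candidate-power scale-free fit summary and the chosen power."""

    table: pd.DataFrame  # power, r2_signed, slope, mean_k, median_k, n_bins
    chosen: int
    target_r2: float


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float, int]:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width connectivity bins."""
    lo, hi = float(k.min()), float(k.max())
    if hi <= lo:
        return np.nan, np.nan, 0
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(max(members.mean(), 1e-12)))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return np.nan, np.nan, len(xs)
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = np.sum((ys - pred) ** 2)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2, slope, len(xs)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    target_r2: float = 0.90,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    For each beta the connectivity k_i = sum_{j != i} a_ij is binned into
    ``n_bins`` equal-width bins and log10(bin frequency) is regressed on
    log10(mean bin k); the signed fit index is -sign(slope) * R^2.  The
    chosen power is the smallest candidate meeting ``target_r2``, else the
    candidate maximizing the signed index.  Powers with fewer than 3
    nonempty bins are flagged (NaN) and excluded from the choice.
    """
    candidate_powers = list(candidate_powers)
    if len(candidate_powers) < 2:
        raise ValueError("need at least two candidate powers")
    expr = _drop_constant(expr, strict=False)
    r = np.clip(np.corrcoef(expr.to_numpy(dtype=float)), -1.0, 1.0)
    absr = np.abs(r)
    np.fill_diagonal(absr, 0.0)

    rows = []
    for beta in candidate_powers:
        k = (absr ** beta).sum(axis=1)
        r2, slope, nb = _scale_free_fit(k, n_bins)
        rows.append({"power": beta, "r2_signed": r2, "slope": slope,
                     "mean_k": k.mean(), "median_k": float(np.median(k)),
                     "n_bins": nb})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["r2_signed"])
    if valid.empty:
        raise ValueError("scale-free fit undefined for every candidate power")
    meeting = valid[valid["r2_signed"] >= target_r2]
    chosen = int(meeting["power"].iloc[0]) if not meeting.empty else int(
        valid.loc[valid["r2_signed"].idxmax(), "power"])
    return SoftThresholdScan(table=table, chosen=chosen, target_r2=target_r2)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    With self-connections excluded (a'_ii = 0):
    TOM_ij = (sum_u a'_iu a'_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    TOM_ii = 1.  The clustering input is ``1 - TOM``.
    """
    A = adjacency.to_numpy(dtype=float)
    if np.abs(A - A.T).max() > 1e-8:
        raise ValueError("adjacency matrix is not symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def average_linkage(dissimilarity: pd.DataFrame) -> np.ndarray:
    """UPGMA merge sequence (scipy linkage encoding) of a square,
    symmetric, zero-diagonal dissimilarity matrix."""
    D = dissimilarity.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("NaN in dissimilarity matrix")
    if np.abs(D - D.T).max() > 1e-8 or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    condensed = squareform(np.maximum(D, 0.0), checks=False)
    return linkage(condensed, method="average")


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    gene_ids: pd.Index,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> pd.Series:
    """Static-height branch cut with a minimum module size.

    The tree is cut at ``cut_height`` (default 0.99 x max merge height);
    connected subtrees below the cut with >= ``min_module_size`` members
    become modules named by size rank from the color palette; everything
    else is "grey".  Ties in size are broken by the lexicographically
    smallest member id, so labels are stable under gene reordering.
    """
    max_h = float(dendrogram[:, 2].max()) if len(dendrogram) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_h
    if not 0.0 < cut_height <= max_h or max_h == 0.0:
        raise ValueError(f"cut height {cut_height} outside (0, {max_h}]")
    flat = fcluster(dendrogram, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=gene_ids, name="module")
    clusters = []
    for cid in np.unique(flat):
        members = gene_ids[flat == cid]
        if len(members) >= min_module_size:
            clusters.append((len(members), min(members), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(clusters):
        labels.loc[members] = _module_name(rank)
    return labels


@dataclass
class ModuleEigengenes:
    """First-PC summaries of each module's standardized expression."""

    eigengenes: pd.DataFrame        # modules x samples, unit-norm scores
    variance_explained: pd.Series   # per module, share of variance on PC1

    @property
    def modules(self) -> pd.Index:
        return self.eigengenes.index


def module_eigengene(expr: pd.DataFrame, labels: pd.Series,
                     include_unassigned: bool = False) -> ModuleEigengenes:
    """Module eigengenes: first right-singular vector of the standardized
    module expression block, sign-anchored to the module mean profile."""
    labels = labels.loc[expr.index]
    modules = [m for m in pd.unique(labels) if include_unassigned or m != UNASSIGNED]
    rows, ve = {}, {}
    for m in sorted(modules):
        block = expr.loc[labels.index[labels == m]].to_numpy(dtype=float)
        sd = block.std(axis=1, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"module {m}: dropping {int((sd == 0).sum())} constant gene(s)")
            block = block[sd > 0]
            sd = sd[sd > 0]
        if block.shape[0] == 0:
            continue
        Z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        scores = Vt[0]
        mean_profile = Z.mean(axis=0)
        if np.dot(scores, mean_profile) < 0:
            scores = -scores
        rows[m] = scores
        ve[m] = float(s[0] ** 2 / np.sum(s ** 2))
    eigengenes = pd.DataFrame(rows, index=expr.columns).T
    eigengenes.index.name = "module"
    return ModuleEigengenes(eigengenes=eigengenes,
                            variance_explained=pd.Series(ve, name="variance_explained"))


def merge_close_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    cut_height: float = 0.15,
    max_rounds: int = 10,
) -> tuple[pd.Series, ModuleEigengenes]:
    """Merge modules whose eigengenes correlate above ``1 - cut_height``.

    Eigengenes are clustered by average linkage on 1 - cor; groups below
    the cut merge (keeping the largest member's name) and eigengenes are
    recomputed; iterate to a fixed point.
    """
    labels = labels.copy()
    for _ in range(max_rounds):
        me = module_eigengene(expr, labels)
        mods = list(me.modules)
        if len(mods) < 2:
            break
        C = np.corrcoef(me.eigengenes.to_numpy(dtype=float))
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D = np.maximum((D + D.T) / 2.0, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(np.unique(groups)) == len(mods):
            break
        sizes = labels.value_counts()
        for gid in np.unique(groups):
            members = [mods[i] for i in np.flatnonzero(groups == gid)]
            if len(members) < 2:
                continue
            keep = max(members, key=lambda m: (sizes.get(m, 0), m))
            labels[labels.isin(members)] = keep
    return labels, module_eigengene(expr, labels)
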