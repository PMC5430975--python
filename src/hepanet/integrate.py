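"""Module-trait correlation, module membership (kME), and module selection.

A module is carried forward when (i) its eigengene correlates with some PK
trait at |r| > 0.30 with p < 0.10 (two-sided Student t on n - 2 df,
treated samples only, since untreated animals have no PK record), and
(ii) at least 10% of its genes are differentially expressed (FDR < 0.05)
in the corresponding treated-vs-untreated contrast.  The unassigned
("grey") group is never selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .netbuild import UNASSIGNED, ModuleEigengenes

__all__ = [
    "cor_pvalue",
    "module_trait_correlations",
    "module_membership",
    "select_modules",
]


def cor_pvalue(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t transform on n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * t_dist.sf(tt, df=n - 2)


def module_trait_correlations(
    eigengenes: ModuleEigengenes | pd.DataFrame,
    traits: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of each module eigengene with
    each PK trait.

    Returns a long table (module, trait, r, p, n).  Pairs with a constant
    trait or fewer than ``min_n`` complete observations are reported with
    NaN r/p and a ``note``.
    """
    me = eigengenes.eigengenes if isinstance(eigengenes, ModuleEigengenes) else eigengenes
    shared = me.columns.intersection(traits.index)
    rows = []
    for module in me.index:
        e = me.loc[module, shared]
        for trait in traits.columns:
            tv = traits.loc[shared, trait]
            ok = tv.notna() & e.notna()
            n = int(ok.sum())
            note = ""
            if n < min_n:
                r = p = np.nan
                note = f"only {n} complete observations"
            elif tv[ok].std(ddof=0) == 0 or e[ok].std(ddof=0) == 0:
                r = p = np.nan
                note = "constant values"
            else:
                r = float(np.corrcoef(e[ok], tv[ok])[0, 1])
                p = float(cor_pvalue(r, n))
            rows.append({"module": module, "trait": trait, "r": r, "p": p,
                         "n": n, "note": note})
    return pd.DataFrame(rows)


def module_membership(
    expr: pd.DataFrame,
    eigengenes: ModuleEigengenes | pd.DataFrame,
) -> pd.DataFrame:
    """Full gene x module kME grid: cor(gene profile, module eigengene)."""
    me = eigengenes.eigengenes if isinstance(eigengenes, ModuleEigengenes) else eigengenes
    shared = expr.columns.intersection(me.columns)
    X = expr[shared].to_numpy(dtype=float)
    E = me[shared].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc ** 2).sum(axis=1))
    es = np.sqrt((Ec ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        kme = (Xc @ Ec.T) / np.outer(xs, es)
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr.index, columns=me.index)


def select_modules(
    trait_table: pd.DataFrame,
    de_results: pd.DataFrame,
    labels: pd.Series,
    r_min: float = 0.30,
    p_max: float = 0.10,
    de_frac_min: float = 0.10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Apply the three-filter module selection.

    A module passes on its best trait (largest |r|): |r| strictly greater
    than ``r_min``, p strictly below ``p_max``, and the share of module
    genes at FDR < ``fdr_threshold`` in the treated-vs-untreated contrast
    at least ``de_frac_min``.  Returns one row per non-grey module.
    """
    if de_results.empty:
        raise ValueError("missing differential-expression results for this arm")
    de_sig = set(de_results.loc[de_results["fdr"] < fdr_threshold, "gene_id"])
    rows = []
    for module in sorted(set(labels) - {UNASSIGNED}):
        genes = labels.index[labels == module]
        de_frac = float(np.mean([g in de_sig for g in genes])) if len(genes) else 0.0
        sub = trait_table[(trait_table["module"] == module) & trait_table["r"].notna()]
        if sub.empty:
            best_trait, r, p = "", np.nan, np.nan
            passes = False
        else:
            best = sub.loc[sub["r"].abs().idxmax()]
            best_trait, r, p = best["trait"], float(best["r"]), float(best["p"])
            passes = (abs(r) > r_min) and (p < p_max) and (de_frac >= de_frac_min)
        rows.append({"module": module, "n_genes": int(len(genes)),
                     "best_trait": best_trait, "r": r, "p": p,
                     "de_fraction": de_frac, "selected": bool(passes)})
    return pd.DataFrame(rows)
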