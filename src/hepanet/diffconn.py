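"""Per-condition scaled connectivity, differential connectivity and hub
calling, and KS comparison of connectivity distributions.

Within a module, connectivity is the sum of a gene's unsigned adjacency to
every other module gene, computed separately in the treated and untreated
sample sets with the same soft-threshold power as the main network, and
divided by the within-network maximum so values lie in [0, 1].  The
differential connectivity dk = k_treated - k_untreated is positive when a
gene is more connected under treatment; genes with |dk| above a threshold
(default 0.6) are flagged as candidate hubs.  The treated and untreated
connectivity distributions are compared with a two-sample two-sided
Kolmogorov-Smirnov test (asymptotic p with the usual effective-n
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .netbuild import adjacency_matrix

__all__ = [
    "KSComparison",
    "scaled_connectivity",
    "differential_connectivity",
    "ks_compare",
]


def scaled_connectivity(
    expr_condition: pd.DataFrame,
    module_genes,
    beta: float,
) -> pd.Series:
    """Within-module scaled connectivity for one condition.

    ``expr_condition`` holds the samples of a single condition (>= 3);
    the adjacency is restricted to ``module_genes`` (>= 2).
    """
    module_genes = pd.Index(module_genes)
    if len(module_genes) < 2:
        raise ValueError("need at least 2 module genes")
    if expr_condition.shape[1] < 3:
        raise ValueError("need at least 3 samples in the condition")
    A = adjacency_matrix(expr_condition.loc[module_genes], beta=beta)
    A0 = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    kmax = k.max()
    if kmax == 0:
        raise ValueError("all-zero adjacency: scaled connectivity undefined")
    return pd.Series(k / kmax, index=A.index, name="k")


def differential_connectivity(
    k_treated: pd.Series,
    k_untreated: pd.Series,
    hub_threshold: float = 0.6,
    hub_on: str = "delta",
) -> pd.DataFrame:
    """Per-gene connectivity difference with hub flags.

    ``hub_on="delta"`` flags |k_treated - k_untreated| > threshold (the
    default reading); ``hub_on="raw"`` instead flags genes whose
    connectivity in either condition exceeds the threshold.
    """
    if set(k_treated.index) != set(k_untreated.index):
        raise ValueError("treated and untreated connectivity cover different genes")
    k_untreated = k_untreated.loc[k_treated.index]
    dk = k_treated - k_untreated
    if hub_on == "delta":
        hub = dk.abs() > hub_threshold
    elif hub_on == "raw":
        hub = (k_treated > hub_threshold) | (k_untreated > hub_threshold)
    else:
        raise ValueError(f"unknown hub_on mode {hub_on!r}")
    return pd.DataFrame({
        "k_treated": k_treated,
        "k_untreated": k_untreated,
        "delta_k": dk,
        "hub": hub,
    })


@dataclass
class KSComparison:
    statistic: float
    pvalue: float
    mean_k_treated: float
    mean_k_untreated: float


def ks_compare(k_treated: pd.Series | np.ndarray,
               k_untreated: pd.Series | np.ndarray) -> KSComparison:
    """Two-sample two-sided KS comparison of connectivity distributions."""
    kt = np.asarray(k_treated, dtype=float)
    ku = np.asarray(k_untreated, dtype=float)
    if kt.size < 5 or ku.size < 5:
        raise ValueError("need at least 5 connectivity values per condition")
    if np.array_equal(np.sort(kt), np.sort(ku)):
        d, p = 0.0, 1.0
    else:
        res = ks_2samp(kt, ku, alternative="two-sided", method="asymp")
        d, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return KSComparison(statistic=d, pvalue=p,
                        mean_k_treated=float(kt.mean()),
                        mean_k_untreated=float(ku.mean()))
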