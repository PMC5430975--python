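"""Term enrichment of module gene sets against the expressed background.

One-sided (enrichment) hypergeometric upper-tail test per term — the tail
of Fisher's exact test — with Benjamini-Hochberg FDR across the terms
tested for each module.  All gene sets are intersected with the expressed
background before testing; empty terms are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr

__all__ = ["AnnotationMap", "enrichment_test"]


@dataclass
class AnnotationMap:
    """term -> gene-set map with optional readable names."""

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_table(cls, annotation: pd.DataFrame) -> "AnnotationMap":
        """Build from the gene_id/term_id(/term_name) long table."""
        term_genes: dict[str, set[str]] = {}
        term_names: dict[str, str] = {}
        for row in annotation.itertuples(index=False):
            term_genes.setdefault(row.term_id, set()).add(row.gene_id)
            name = getattr(row, "term_name", None)
            if name is not None and row.term_id not in term_names:
                term_names[row.term_id] = name
        return cls(term_genes=term_genes, term_names=term_names)

    def restricted_to(self, background: set[str]) -> "AnnotationMap":
        genes = {t: g & background for t, g in self.term_genes.items()}
        return AnnotationMap(term_genes={t: g for t, g in genes.items() if g},
                             term_names=self.term_names)


def enrichment_test(
    module_genes,
    annotation: AnnotationMap | pd.DataFrame,
    background,
    module: str = "module",
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of one module over all terms.

    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=term size,
    n=module size); FDR is BH across the terms tested for this module.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = AnnotationMap.from_table(annotation)
    background = set(background)
    module_set = set(module_genes)
    stray = module_set - background
    if stray:
        raise ValueError(
            f"{len(stray)} module gene(s) missing from the background, e.g. "
            f"{sorted(stray)[0]}")
    ann = annotation.restricted_to(background)
    N, n = len(background), len(module_set)
    rows = []
    for term, genes in sorted(ann.term_genes.items()):
        K = len(genes)
        overlap = len(module_set & genes)
        p = float(hypergeom.sf(overlap - 1, N, K, n))
        rows.append({
            "module": module, "term_id": term,
            "term_name": ann.term_names.get(term, term),
            "overlap": overlap, "module_size": n, "term_size": K,
            "background_size": N, "pvalue": min(p, 1.0),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
        out = out.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    return out
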