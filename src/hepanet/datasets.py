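"""Core in-memory containers shared across the pipeline stages.

Everything is pandas-backed: genes index rows, samples index columns, and
every transform preserves both label sets so provenance can be audited at
any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Pharmacokinetic trait columns, in canonical order: half-life (h), area
#: under the concentration-time curve (h*ug/mL), clearance (L/h/kg), mean
#: residence time (h), volume of distribution at steady state (L/kg), peak
#: concentration (ug/mL) and time of peak concentration (h).
PK_TRAITS = ("T12", "AUC", "CL", "MRT", "VDSS", "CMAX", "TMAX")

TREATMENTS = ("FBZ", "FLU", "UNT")
BREEDS = ("D", "H", "L", "Y")
SEXES = ("F", "CM")


@dataclass
class CountDataset:
    """Gene-level count matrix plus the per-gene and per-sample annotations.

    Attributes
    ----------
    counts
        genes x samples matrix of nonnegative integer read counts.
    gene_lengths
        Per-gene transcript length in bp, indexed like ``counts``.
    samples
        Per-sample metadata with columns ``treatment`` (FBZ/FLU/UNT),
        ``breed``, ``sex`` and ``batch``; indexed by sample id in the same
        order as the count columns.
    traits
        Per-sample pharmacokinetic parameters (columns from
        :data:`PK_TRAITS`); rows for untreated animals may be all-NaN since
        no drug was administered to them.
    annotation
        Optional gene -> functional-term map with columns ``gene_id``,
        ``term_id``, ``term_name`` (one row per pair).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame
    traits: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("count columns and sample metadata rows disagree")
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("count rows and gene lengths disagree")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise ValueError(f"nonpositive gene length for {bad}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountDataset":
        """Restrict to the given samples (gene set unchanged)."""
        sample_ids = pd.Index(sample_ids)
        traits = None if self.traits is None else self.traits.loc[self.traits.index.intersection(sample_ids)]
        return CountDataset(
            counts=self.counts.loc[:, sample_ids],
            gene_lengths=self.gene_lengths,
            samples=self.samples.loc[sample_ids],
            traits=traits,
            annotation=self.annotation,
        )

    def subset_genes(self, gene_ids) -> "CountDataset":
        gene_ids = pd.Index(gene_ids)
        return CountDataset(
            counts=self.counts.loc[gene_ids],
            gene_lengths=self.gene_lengths.loc[gene_ids],
            samples=self.samples,
            traits=self.traits,
            annotation=self.annotation,
        )


@dataclass
class NormalizationFactors:
    """Library sizes and TMM scaling factors.

    ``effective_sizes = library_sizes * tmm_factors``; the TMM factors are
    rescaled to geometric mean 1 so effective sizes stay on the raw
    library-size scale.
    """

    library_sizes: pd.Series
    tmm_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0][0]
            raise ValueError(f"zero library size for sample {bad}")

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors

    @classmethod
    def unit(cls, library_sizes: pd.Series) -> "NormalizationFactors":
        """Factors of 1 everywhere (plain library-size normalization)."""
        return cls(library_sizes=library_sizes,
                   tmm_factors=pd.Series(1.0, index=library_sizes.index))


@dataclass
class ExprMatrix:
    """A normalized expression matrix with a scale tag and provenance trail."""

    values: pd.DataFrame
    scale: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.asarray(self.values.isna()).any():
            raise ValueError("expression matrix contains missing values")

    def with_values(self, values: pd.DataFrame, scale: str, step: str) -> "ExprMatrix":
        return ExprMatrix(values=values, scale=scale, provenance=[*self.provenance, step])

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
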