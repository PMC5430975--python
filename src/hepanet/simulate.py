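"""Synthetic liver RNA-seq study generator with planted ground truth.

The generator emulates the design of a 60-animal pharmacokinetic (PK)
transcriptome study: one drug arm at a time (20 treated + 20 untreated
animals, 5 housing batches, 4 sire breeds, 2 sexes), negative-binomial
gene counts on top of log-scale means, planted co-expression modules
driven by per-sample latent "pathway activity" factors, a configurable
fraction of treatment-responsive genes, multiplicative batch effects, and
PK traits that are noisy linear functions of a module's latent factor.

Every planted feature is returned in a :class:`GroundTruth` object so each
downstream stage (normalization, differential expression, network
construction, module-trait integration, differential connectivity,
enrichment) can be tested against a known answer without any external
data.

Model
-----
For gene g in sample s the log-scale mean is

    log mu_gs = base_g + lambda_g * f_{m(g),s} + d_g * t_s * ln 2 + b_{g,batch(s)}

where ``f_{m,s}`` is the module latent factor (standardized to zero mean
and unit variance within each treatment condition, so planted correlation
levels hold exactly in-sample), ``lambda_g = strength * (1 + gain)`` for
treated samples and ``strength`` otherwise, ``d_g`` is the planted log2
fold change for treatment-responsive genes (``t_s`` = 1 for treated), and
``b`` are per-(gene, batch) Gaussian log offsets.  Counts are drawn as
NB(mu, phi_g) with gamma-distributed gene dispersions.  Background genes
carry no factor: their only variation is the NB observation noise, which
gives the module detection stage an unambiguous "unassigned" truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CountDataset, PK_TRAITS

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "write_dataset",
    "read_truth",
]

# Realistic (mean, sd) scales per PK trait used to place the standardized
# trait values on interpretable units. Clearance scales differ per drug
# (fenbendazole clears far slower than flunixin in swine).
TRAIT_SCALES = {
    "T12": (6.0, 2.0),
    "AUC": (15.0, 5.0),
    "CL": {"FBZ": (0.12, 0.04), "FLU": (0.27, 0.22)},
    "MRT": (8.0, 3.0),
    "VDSS": (1.0, 0.3),
    "CMAX": (4.0, 1.5),
    "TMAX": (1.5, 0.5),
}


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    Parameters
    ----------
    module_id
        Identifier used in the ground truth ("M1", "M2", ...).
    n_genes
        Module size.
    latent_factor_strength
        Target correlation between each module gene's log expression and
        the module's latent factor, in [0, 1]; the gene's log-scale factor
        loading is scaled against its own observation-noise level
        (sqrt(phi_g + 1/mu_g)) so the planted correlation is uniform
        across expression depths, and the gene-gene correlation within
        the module is approximately strength squared.  0 disables the
        factor.
    trait_correlation_target
        Target Pearson correlation between the module factor and its PK
        trait across treated samples, in [-1, 1].  0 leaves the trait
        unlinked.
    connectivity_gain_treated
        Relative loading increase in treated samples; loadings become
        ``strength * (1 + gain)``, so co-expression is tighter under
        treatment (>= 0).
    trait
        PK trait driven by this module's factor; one of
        :data:`~hepanet.datasets.PK_TRAITS`.  Ignored when the correlation
        target is 0.
    de_fraction
        Per-module override of the treatment-responsive gene fraction;
        ``None`` falls back to the config-wide
        ``de_fraction_per_module``.
    """

    module_id: str
    n_genes: int
    latent_factor_strength: float = 0.85
    trait_correlation_target: float = 0.0
    connectivity_gain_treated: float = 0.0
    trait: str | None = None
    de_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.latent_factor_strength <= 1.0:
            raise ValueError(f"{self.module_id}: strength must be in [0, 1]")
        if not -1.0 <= self.trait_correlation_target <= 1.0:
            raise ValueError(f"{self.module_id}: trait correlation target must be in [-1, 1]")
        if self.connectivity_gain_treated < 0:
            raise ValueError(f"{self.module_id}: connectivity gain must be >= 0")
        if self.n_genes < 1:
            raise ValueError(f"{self.module_id}: empty module")
        if self.trait is not None and self.trait not in PK_TRAITS:
            raise ValueError(f"{self.module_id}: unknown PK trait {self.trait!r}")
        if self.de_fraction is not None and not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError(f"{self.module_id}: de_fraction must be in [0, 1]")


def default_module_specs() -> tuple[ModuleSpec, ...]:
    """Four planted modules mirroring the size / trait-correlation regime of
    PK-linked liver modules (sizes 80-250, |r| targets 0.38-0.50)."""
    return (
        ModuleSpec("M1", 250, 0.85, -0.44, 0.65, "CL"),
        ModuleSpec("M2", 180, 0.85, 0.50, 0.65, "TMAX"),
        ModuleSpec("M3", 120, 0.85, -0.42, 0.65, "T12"),
        ModuleSpec("M4", 80, 0.85, -0.38, 0.65, "MRT"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic drug arm.

    Defaults reproduce the study conditions: ~12,000 expressed genes, 20
    treated + 20 untreated animals over 5 batches, 4 planted modules
    correlated with PK traits, moderate NB dispersion (gamma with mean
    0.1), and mild multiplicative batch effects.
    """

    n_genes: int = 12000
    n_treated: int = 20
    n_untreated: int = 20
    n_batches: int = 5
    drug: str = "FBZ"
    module_specs: tuple[ModuleSpec, ...] = field(default_factory=default_module_specs)
    de_fraction_per_module: float = 0.15
    de_fraction_background: float = 0.05
    de_log2fc: float = 1.5
    nb_dispersion_shape: float = 2.0
    nb_dispersion_scale: float = 0.05
    batch_sd: float = 0.1
    base_log_mean: float = float(np.log(100.0))
    base_log_sd: float = 1.0
    gene_length_range: tuple[int, int] = (200, 15000)
    n_terms: int = 40
    mean_terms_per_gene: float = 2.0
    term_enrichment: tuple[tuple[str, str, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drug not in ("FBZ", "FLU"):
            raise ValueError("drug must be FBZ or FLU")
        total = sum(m.n_genes for m in self.module_specs)
        if total > self.n_genes:
            raise ValueError(
                f"module genes ({total}) exceed n_genes ({self.n_genes})")
        for frac in (self.de_fraction_per_module, self.de_fraction_background):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("DE fractions must be in [0, 1]")
        if self.nb_dispersion_shape <= 0 or self.nb_dispersion_scale < 0:
            raise ValueError("nonpositive NB dispersion parameters")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        if self.gene_length_range[0] < 1 or self.gene_length_range[1] <= self.gene_length_range[0]:
            raise ValueError("invalid gene length range")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        traits = [m.trait for m in self.module_specs
                  if m.trait is not None and m.trait_correlation_target != 0.0]
        if len(traits) != len(set(traits)):
            raise ValueError("each PK trait may be driven by at most one module")

    def resolved_term_enrichment(self) -> tuple[tuple[str, str, float], ...]:
        """Default: each planted module enriched (50%) in its own term."""
        if self.term_enrichment is not None:
            return self.term_enrichment
        return tuple(
            (m.module_id, f"T{i + 1:03d}", 0.5)
            for i, m in enumerate(self.module_specs)
            if i < self.n_terms
        )


@dataclass
class GroundTruth:
    """Planted structure of a simulated arm, for validation of every stage."""

    module_assignment: pd.Series          # gene -> module_id or "background"
    de_genes: set[str]
    de_log2fc: pd.Series                  # signed planted log2FC, DE genes only
    trait_loadings: dict[str, dict]       # module -> {"trait": ..., "target": ...}
    latent_factors: pd.DataFrame          # module x sample (standardized)
    batch_effects: pd.DataFrame           # batch -> {"mean","sd"} of gene log offsets
    enriched_terms: list[tuple[str, str, float]]

    def module_genes(self, module_id: str) -> pd.Index:
        return self.module_assignment.index[self.module_assignment == module_id]


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_dataset(config: SimulationConfig) -> tuple[CountDataset, GroundTruth]:
    """Draw one synthetic drug arm.

    Returns the count bundle (counts, lengths, sample metadata, PK traits,
    term annotation) and the planted :class:`GroundTruth`.  Identical
    configs (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    nt, nu = config.n_treated, config.n_untreated
    n = nt + nu

    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(G)], name="gene_id")
    sample_ids = pd.Index(
        [f"{config.drug}_{i + 1:02d}" for i in range(nt)]
        + [f"UNT_{i + 1:02d}" for i in range(nu)],
        name="sample_id",
    )
    treated_mask = np.r_[np.ones(nt, bool), np.zeros(nu, bool)]

    # --- sample metadata: treatments fixed; breed/sex/batch balanced ---
    breeds = ["D", "H", "L", "Y"]
    sexes = ["F", "CM"]
    samples = pd.DataFrame(
        {
            "treatment": np.where(treated_mask, config.drug, "UNT"),
            "breed": [breeds[i % 4] for i in range(nt)] + [breeds[i % 4] for i in range(nu)],
            "sex": [sexes[(i // 4) % 2] for i in range(nt)] + [sexes[(i // 4) % 2] for i in range(nu)],
            "batch": [(i % config.n_batches) + 1 for i in range(nt)]
            + [(i % config.n_batches) + 1 for i in range(nu)],
        },
        index=sample_ids,
    )

    # --- gene-level draws ---
    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=G),
        index=gene_ids, name="length_bp",
    )
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=G)
    dispersions = rng.gamma(config.nb_dispersion_shape, config.nb_dispersion_scale, size=G)
    dispersions = np.maximum(dispersions, 1e-8)

    # --- module assignment: random disjoint gene subsets ---
    perm = rng.permutation(G)
    assignment = pd.Series("background", index=gene_ids, name="module")
    pos = 0
    for spec in config.module_specs:
        idx = perm[pos:pos + spec.n_genes]
        assignment.iloc[idx] = spec.module_id
        pos += spec.n_genes

    # --- latent factors, standardized within condition so the planted
    #     correlation level is exact in-sample.  Each gene's loading is
    #     scaled by its own log-scale observation-noise level so the
    #     planted gene-factor correlation is uniform across depths. ---
    eta = np.tile(base[:, None], (1, n))
    noise_sd = np.sqrt(dispersions + 1.0 / np.exp(base))  # delta method
    factors = {}
    for spec in config.module_specs:
        f = rng.normal(0.0, 1.0, size=n)
        if nt > 1:
            f[treated_mask] = _standardize(f[treated_mask])
        if nu > 1:
            f[~treated_mask] = _standardize(f[~treated_mask])
        factors[spec.module_id] = f
        s = spec.latent_factor_strength
        if s > 0:
            s = min(s, 0.999)
            cond_mult = np.where(treated_mask,
                                 1.0 + spec.connectivity_gain_treated, 1.0)
            rows = np.flatnonzero((assignment == spec.module_id).to_numpy())
            load = (s / np.sqrt(1.0 - s * s)) * noise_sd[rows]
            eta[rows] += load[:, None] * (cond_mult * f)[None, :]
    latent = pd.DataFrame(
        {m: factors[m] for m in factors}, index=sample_ids
    ).T
    latent.index.name = "module"

    # --- treatment effects ---
    de_effect = np.zeros(G)
    for spec in config.module_specs:
        rows = np.flatnonzero((assignment == spec.module_id).to_numpy())
        frac = (spec.de_fraction if spec.de_fraction is not None
                else config.de_fraction_per_module)
        n_de = int(round(frac * len(rows)))
        chosen = rng.choice(rows, size=n_de, replace=False)
        de_effect[chosen] = config.de_log2fc * rng.choice([-1.0, 1.0], size=n_de)
    bg_rows = np.flatnonzero((assignment == "background").to_numpy())
    n_de_bg = int(round(config.de_fraction_background * len(bg_rows)))
    if n_de_bg:
        chosen = rng.choice(bg_rows, size=n_de_bg, replace=False)
        de_effect[chosen] = config.de_log2fc * rng.choice([-1.0, 1.0], size=n_de_bg)
    eta += np.log(2.0) * de_effect[:, None] * treated_mask[None, :]

    # --- batch effects: per-(gene, batch) log-normal multipliers ---
    batch_idx = samples["batch"].to_numpy() - 1
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(G, config.n_batches))
    if config.batch_sd == 0:
        batch_offsets[:] = 0.0
    eta += batch_offsets[:, batch_idx]
    batch_summary = pd.DataFrame(
        {
            "mean": batch_offsets.mean(axis=0),
            "sd": batch_offsets.std(axis=0),
        },
        index=pd.Index(range(1, config.n_batches + 1), name="batch"),
    )

    # --- NB observation model ---
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    r = 1.0 / dispersions[:, None]
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    counts = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    # --- PK traits: noisy linear responses to the module factors, treated
    #     samples only (untreated animals received no drug) ---
    traits = pd.DataFrame(np.nan, index=sample_ids, columns=list(PK_TRAITS))
    trait_loadings: dict[str, dict] = {}
    driven = {}
    for spec in config.module_specs:
        if spec.trait is not None and spec.trait_correlation_target != 0.0:
            driven[spec.trait] = spec
            trait_loadings[spec.module_id] = {
                "trait": spec.trait, "target": spec.trait_correlation_target,
            }
    for trait in PK_TRAITS:
        scale = TRAIT_SCALES[trait]
        if isinstance(scale, dict):
            scale = scale[config.drug]
        mean, sd = scale
        noise = rng.normal(0.0, 1.0, size=nt)
        if trait in driven and nt >= 3:
            spec = driven[trait]
            z = factors[spec.module_id][treated_mask]
            # orthogonalize the noise against the factor so the planted
            # factor-trait correlation is exact in-sample
            noise = noise - z * (noise @ z) / (z @ z)
            noise = _standardize(noise)
            rho = spec.trait_correlation_target
            x = rho * z + np.sqrt(1.0 - rho * rho) * noise
        else:
            x = _standardize(noise) if nt > 1 else noise
        traits.loc[treated_mask, trait] = mean + sd * x

    # --- term annotation, enriched in the requested modules ---
    annotation = _simulate_annotation(config, rng, gene_ids, assignment)

    dataset = CountDataset(
        counts=counts, gene_lengths=lengths, samples=samples,
        traits=traits, annotation=annotation,
    )
    truth = GroundTruth(
        module_assignment=assignment,
        de_genes=set(gene_ids[de_effect != 0]),
        de_log2fc=pd.Series(de_effect[de_effect != 0], index=gene_ids[de_effect != 0]),
        trait_loadings=trait_loadings,
        latent_factors=latent,
        batch_effects=batch_summary,
        enriched_terms=list(config.resolved_term_enrichment()),
    )
    return dataset, truth


def _simulate_annotation(config, rng, gene_ids, assignment) -> pd.DataFrame:
    term_ids = [f"T{i + 1:03d}" for i in range(config.n_terms)]
    rows: list[tuple[str, str]] = []
    n_terms_per_gene = rng.poisson(config.mean_terms_per_gene, size=len(gene_ids))
    for gid, k in zip(gene_ids, n_terms_per_gene):
        if k == 0:
            continue
        for t in rng.choice(config.n_terms, size=min(k, config.n_terms), replace=False):
            rows.append((gid, term_ids[t]))
    for module_id, term_id, frac in config.resolved_term_enrichment():
        members = assignment.index[assignment == module_id]
        n_extra = int(np.ceil(frac * len(members)))
        chosen = rng.choice(len(members), size=n_extra, replace=False)
        rows.extend((members[i], term_id) for i in chosen)
    ann = pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates()
    ann = ann.sort_values(["gene_id", "term_id"], kind="mergesort").reset_index(drop=True)
    ann["term_name"] = "synthetic process " + ann["term_id"].str[1:]
    return ann


# ---------------------------------------------------------------------------
# serialization

def write_dataset(dataset: CountDataset, truth: GroundTruth | None, directory) -> dict[str, Path]:
    """Write the TSV bundle (+ truth.json) and return the paths written.

    The files round-trip losslessly through :func:`hepanet.io.read_dataset`
    / :func:`read_truth`.
    """
    from . import io as hio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = hio.write_dataset(dataset, directory)
    if truth is not None:
        tpath = directory / "truth.json"
        payload = {
            "module_assignment": truth.module_assignment.to_dict(),
            "de_genes": sorted(truth.de_genes),
            "de_log2fc": truth.de_log2fc.to_dict(),
            "trait_loadings": truth.trait_loadings,
            "latent_factors": {
                "modules": list(truth.latent_factors.index),
                "samples": list(truth.latent_factors.columns),
                "values": truth.latent_factors.to_numpy().tolist(),
            },
            "batch_effects": {
                "batches": [int(b) for b in truth.batch_effects.index],
                "mean": truth.batch_effects["mean"].tolist(),
                "sd": truth.batch_effects["sd"].tolist(),
            },
            "enriched_terms": [list(t) for t in truth.enriched_terms],
        }
        tpath.write_text(json.dumps(payload, indent=1, sort_keys=True))
        paths["truth"] = tpath
    return paths


def read_truth(path) -> GroundTruth:
    """Reload a truth.json written by :func:`write_dataset`."""
    payload = json.loads(Path(path).read_text())
    lf = payload["latent_factors"]
    latent = pd.DataFrame(lf["values"],
                          index=pd.Index(lf["modules"], name="module"),
                          columns=pd.Index(lf["samples"], name="sample_id"))
    be = payload["batch_effects"]
    batch = pd.DataFrame({"mean": be["mean"], "sd": be["sd"]},
                         index=pd.Index(be["batches"], name="batch"))
    assignment = pd.Series(payload["module_assignment"], name="module")
    assignment.index.name = "gene_id"
    assignment = assignment.sort_index()
    de_fc = pd.Series(payload["de_log2fc"], dtype=float).sort_index()
    de_fc.index.name = "gene_id"
    return GroundTruth(
        module_assignment=assignment,
        de_genes=set(payload["de_genes"]),
        de_log2fc=de_fc,
        trait_loadings=payload["trait_loadings"],
        latent_factors=latent,
        batch_effects=batch,
        enriched_terms=[tuple(t) for t in payload["enriched_terms"]],
    )
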