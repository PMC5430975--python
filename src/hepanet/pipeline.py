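"""Per-arm orchestration: filter -> normalize -> DE -> batch-adjust ->
network -> modules -> trait correlation -> selection -> connectivity ->
KS -> enrichment.

One "arm" is a drug group (FBZ or FLU) together with the shared untreated
animals.  Gene filtering is computed once across every sample in the
input bundle (the full-study matrix) before the arm is split out.
Module detection runs on the treated samples; the untreated samples
provide the second network for differential connectivity.  Every stage
writes its table under the run directory and contributes to a
machine-readable ``summary.json``; reruns on identical inputs and seed
are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .datasets import CountDataset, ExprMatrix
from .diffexpr import (build_design, estimate_dispersions, fit_nb_glm,
                       interaction_contrast, lrt_contrast, treatment_contrast)
from .diffconn import differential_connectivity, ks_compare, scaled_connectivity
from .enrich import AnnotationMap, enrichment_test
from .integrate import module_membership, module_trait_correlations, select_modules
from .netbuild import (UNASSIGNED, adjacency_matrix, average_linkage,
                       dynamic_tree_cut, merge_close_modules, module_eigengene,
                       pick_soft_threshold, tom_similarity)
from .preprocess import (compute_cpm, compute_rpkm, filter_low_expression,
                         library_sizes, log2_transform, mds_top_sd,
                         remove_batch_effect, tmm_factors)

__all__ = ["RunConfig", "run_arm"]


@dataclass
class RunConfig:
    """Resolved parameters of one arm analysis.

    Defaults equal the study's printed settings: CPM > 1 in >= 5 samples,
    soft power chosen by the scale-free criterion (target R^2 0.90) from
    candidates 1..20, minimum module size 30, eigengene merge height 0.15
    (r > 0.85), module selection at |r| > 0.30 & p < 0.10 & >= 10% DE,
    hub threshold |dk| > 0.6, FDR 0.05.
    """

    data_dir: str = "."
    arm: str = "FBZ"
    out_dir: str = "results/run"
    min_cpm: float = 1.0
    min_samples: int = 5
    beta: int | None = None            # None -> scale-free scan
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.90
    min_module_size: int = 30
    tree_cut_height_frac: float = 0.99
    merge_cut_height: float = 0.15
    r_min: float = 0.30
    p_max: float = 0.10
    de_frac_min: float = 0.10
    hub_threshold: float = 0.6
    hub_on: str = "delta"
    fdr: float = 0.05
    rpkm_library: str = "effective"    # "effective" (TMM) or "raw"
    log_prior: float = 1.0
    mds_top_genes: int = 500
    interaction_contrasts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("FBZ", "FLU"):
            raise ValueError("arm must be FBZ or FLU")
        if self.rpkm_library not in ("effective", "raw"):
            raise ValueError("rpkm_library must be 'effective' or 'raw'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "candidate_powers" in payload:
            payload["candidate_powers"] = tuple(payload["candidate_powers"])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["candidate_powers"] = list(self.candidate_powers)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _treated_mask(samples: pd.DataFrame, arm: str) -> pd.Series:
    return samples["treatment"] == arm


#: pipeline stage order; ``run_arm(stop_after=...)`` stops after the named one
STAGES = ("filter", "normalize", "expression", "diffexpr", "network",
          "integrate", "diffconn", "enrich")


def run_arm(config: RunConfig, dataset: CountDataset | None = None,
            stop_after: str | None = None) -> dict:
    """Execute the arm analysis; returns the run summary dict.

    ``dataset`` may be passed directly (e.g. from the simulator); otherwise
    it is loaded from ``config.data_dir``.  ``stop_after`` runs the
    pipeline only through the named stage (see :data:`STAGES`).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = hio.read_dataset(config.data_dir)

    # --- preconditions -----------------------------------------------------
    treatments = set(dataset.samples["treatment"])
    if config.arm not in treatments:
        raise ValueError(f"no treated ({config.arm}) samples in the dataset")
    if "UNT" not in treatments:
        raise ValueError("no untreated (UNT) samples in the dataset")

    summary: dict = {"config": {**asdict(config),
                                "candidate_powers": list(config.candidate_powers)},
                     "stages": {}}

    def finalize() -> dict:
        summary["elapsed_s"] = round(time.time() - t0, 3)
        summary["seed"] = config.seed
        config.to_yaml(out / "config_resolved.yaml")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        return summary

    def stage(name: str, **stats) -> bool:
        """Record stage stats; True when the pipeline should stop here."""
        summary["stages"][name] = {**stats, "elapsed_s": round(time.time() - t0, 3)}
        return stop_after == name

    # --- filtering (joint across every sample in the bundle) ---------------
    n_genes_initial = dataset.counts.shape[0]
    cpm_raw = compute_cpm(dataset)
    kept = filter_low_expression(cpm_raw, config.min_cpm, config.min_samples)
    dataset_f = dataset.subset_genes(kept)
    if stage("filter", genes_initial=n_genes_initial, genes_kept=len(kept),
             min_cpm=config.min_cpm, min_samples=config.min_samples):
        return finalize()

    # --- split out the arm --------------------------------------------------
    in_arm = dataset_f.samples["treatment"].isin([config.arm, "UNT"])
    arm_ds = dataset_f.subset_samples(dataset_f.sample_ids[in_arm])
    treated = _treated_mask(arm_ds.samples, config.arm)

    # --- normalization ------------------------------------------------------
    factors = tmm_factors(arm_ds)
    hio.write_table(
        pd.DataFrame({"sample_id": factors.library_sizes.index,
                      "library_size": factors.library_sizes.to_numpy(),
                      "tmm_factor": factors.tmm_factors.to_numpy(),
                      "effective_size": factors.effective_sizes.to_numpy()}),
        out / "norm_factors.tsv")
    cpm = compute_cpm(arm_ds, factors)
    logcpm = log2_transform(cpm, config.log_prior)
    mds = mds_top_sd(logcpm, n_top=config.mds_top_genes, n_dims=2)
    hio.write_table(mds.reset_index(), out / "mds.tsv")
    if stage("normalize", samples=int(arm_ds.counts.shape[1]),
             tmm_range=[float(factors.tmm_factors.min()),
                        float(factors.tmm_factors.max())],
             mds_variance_explained=[float(v) for v in
                                     mds.attrs["variance_explained"]]):
        return finalize()

    # --- batch-adjusted log RPKM for the network stages ---------------------
    rpkm = compute_rpkm(
        arm_ds,
        factors if config.rpkm_library == "effective" else None)
    logrpkm = log2_transform(rpkm, config.log_prior)
    preserve = pd.DataFrame(
        {"intercept": 1.0, "treated": treated.astype(float)},
        index=arm_ds.sample_ids)
    adjusted = remove_batch_effect(logrpkm, arm_ds.samples["batch"], preserve)
    expr = adjusted.values
    hio.write_table(expr.reset_index(), out / "expr_adjusted.tsv")
    expr_treated = expr.loc[:, treated.to_numpy()]
    expr_untreated = expr.loc[:, (~treated).to_numpy()]
    if stage("expression", scale=adjusted.scale,
             provenance=adjusted.provenance):
        return finalize()

    # --- differential expression -------------------------------------------
    offsets = np.log(factors.effective_sizes.to_numpy())
    design = build_design(arm_ds.samples, "overall")
    disp = estimate_dispersions(arm_ds.counts, design, offsets)
    fit = fit_nb_glm(arm_ds.counts, design, offsets, disp)
    de_tables = [lrt_contrast(fit, arm_ds.counts, offsets, disp,
                              treatment_contrast(design),
                              label=f"{config.arm}_vs_UNT")]
    if config.interaction_contrasts:
        de_tables.extend(_interaction_tables(arm_ds, offsets, config.arm))
    de_results = pd.concat(de_tables, ignore_index=True)
    hio.write_table(de_results, out / "de_results.tsv")
    de_main = de_results[de_results["contrast"] == f"{config.arm}_vs_UNT"]
    n_de = int((de_main["fdr"] < config.fdr).sum())
    if stage("diffexpr", common_dispersion=disp.common,
             n_contrasts=len(de_tables), n_de_main=n_de):
        return finalize()

    # --- network construction (treated samples) ----------------------------
    scan = pick_soft_threshold(expr_treated, config.candidate_powers,
                               config.target_r2)
    hio.write_table(scan.table, out / "soft_threshold_scan.tsv")
    beta = scan.chosen if config.beta is None else int(config.beta)
    at_beta = scan.table.loc[scan.table["power"] == beta, "r2_signed"]
    r2_at_beta = float(at_beta.iloc[0]) if len(at_beta) else float("nan")
    adj = adjacency_matrix(expr_treated, beta=beta)
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss.values, 0.0)
    dendro = average_linkage(diss)
    labels = dynamic_tree_cut(dendro, adj.index,
                              min_module_size=config.min_module_size,
                              cut_height=config.tree_cut_height_frac
                              * float(dendro[:, 2].max()))
    labels, me = merge_close_modules(expr_treated.loc[labels.index], labels,
                                     cut_height=config.merge_cut_height)
    hio.write_table(labels.rename("module").reset_index(), out / "modules.tsv")
    hio.write_table(me.eigengenes.reset_index(), out / "eigengenes.tsv")
    module_sizes = labels[labels != UNASSIGNED].value_counts()
    if stage("network", beta=int(beta), scale_free_r2=r2_at_beta,
             n_modules=int(len(module_sizes)),
             n_unassigned=int((labels == UNASSIGNED).sum()),
             module_sizes=module_sizes.to_dict()):
        return finalize()

    # --- module-trait integration ------------------------------------------
    traits = arm_ds.traits
    if traits is None:
        raise ValueError("dataset has no PK trait table")
    traits_treated = traits.loc[arm_ds.sample_ids[treated.to_numpy()]]
    trait_tbl = module_trait_correlations(me, traits_treated)
    hio.write_table(trait_tbl, out / "module_trait.tsv")
    kme = module_membership(expr_treated, me)
    hio.write_table(kme.reset_index(), out / "module_membership.tsv")
    selection = select_modules(trait_tbl, de_main, labels,
                               r_min=config.r_min, p_max=config.p_max,
                               de_frac_min=config.de_frac_min,
                               fdr_threshold=config.fdr)
    hio.write_table(selection, out / "module_selection.tsv")
    selected = selection.loc[selection["selected"], "module"].tolist()
    if stage("integrate", n_modules_tested=int(len(selection)),
             n_selected=len(selected), selected=selected):
        return finalize()

    # --- differential connectivity within selected modules ------------------
    conn_rows, ks_rows = [], []
    for module in selected:
        genes = labels.index[labels == module]
        kt = scaled_connectivity(expr_treated, genes, beta)
        ku = scaled_connectivity(expr_untreated, genes, beta)
        prof = differential_connectivity(kt, ku, config.hub_threshold, config.hub_on)
        prof.insert(0, "module", module)
        conn_rows.append(prof.rename_axis("gene_id").reset_index())
        ks = ks_compare(kt, ku)
        ks_rows.append({"module": module, "D": ks.statistic, "pvalue": ks.pvalue,
                        "mean_k_treated": ks.mean_k_treated,
                        "mean_k_untreated": ks.mean_k_untreated})
    connectivity = (pd.concat(conn_rows, ignore_index=True) if conn_rows
                    else pd.DataFrame(columns=["gene_id", "module", "k_treated",
                                               "k_untreated", "delta_k", "hub"]))
    ks_tests = pd.DataFrame(ks_rows, columns=["module", "D", "pvalue",
                                              "mean_k_treated", "mean_k_untreated"])
    hio.write_table(connectivity, out / "connectivity.tsv")
    hio.write_table(ks_tests, out / "ks_tests.tsv")
    if stage("diffconn",
             n_hubs=int(connectivity["hub"].sum()) if len(connectivity) else 0,
             ks=[{k: (round(v, 6) if isinstance(v, float) else v)
                  for k, v in row.items()} for row in ks_rows]):
        return finalize()

    # --- enrichment ----------------------------------------------------------
    enrich_rows = []
    if dataset.annotation is not None:
        ann = AnnotationMap.from_table(dataset.annotation)
        background = set(labels.index)
        for module in selected:
            genes = set(labels.index[labels == module])
            enrich_rows.append(enrichment_test(genes, ann, background, module=module))
    enrichment = (pd.concat(enrich_rows, ignore_index=True) if enrich_rows
                  else pd.DataFrame(columns=["module", "term_id", "term_name",
                                             "overlap", "module_size", "term_size",
                                             "background_size", "pvalue", "fdr"]))
    hio.write_table(enrichment, out / "enrichment.tsv")
    n_sig_terms = int((enrichment["fdr"] < config.fdr).sum()) if len(enrichment) else 0
    stage("enrich", n_terms_significant=n_sig_terms)
    return finalize()


def _interaction_tables(arm_ds: CountDataset, offsets: np.ndarray, arm: str) -> list[pd.DataFrame]:
    """Pairwise breed and sex interaction contrasts, batch-adjusted."""
    tables = []
    for scheme, col in (("by_breed", "breed"), ("by_sex", "sex")):
        if col not in arm_ds.samples.columns:
            continue
        design = build_design(arm_ds.samples, scheme)
        disp = estimate_dispersions(arm_ds.counts, design, offsets)
        fit = fit_nb_glm(arm_ds.counts, design, offsets, disp)
        groups = sorted(pd.unique(arm_ds.samples[col]))
        pairs = ([(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
                 if col == "breed" else
                 [(groups[0], groups[1])] if len(groups) == 2 else [])
        for a, b in pairs:
            try:
                c = interaction_contrast(design, a, b)
            except ValueError:
                continue  # cell empty in this layout
            tables.append(lrt_contrast(fit, arm_ds.counts, offsets, disp, c,
                                       label=f"{arm}_{col}_{a}_vs_{b}"))
    return tables
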