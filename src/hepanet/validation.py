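"""Statistical validation studies for the pipeline.

Each function runs one self-contained study against planted ground truth
or an independent oracle and returns a small dict of summary numbers.
They are shared by the acceptance test suite and by
``scripts/acceptance.py``; problem sizes are chosen so the full set runs
in a few minutes on one CPU (see docs/methods.md for the rationale).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datasets import ExprMatrix
from .diffexpr import (bh_fdr, build_design, estimate_dispersions, fit_nb_glm,
                       lrt_contrast, treatment_contrast)
from .diffconn import ks_compare, scaled_connectivity
from .integrate import module_trait_correlations, select_modules
from .netbuild import (UNASSIGNED, adjacency_matrix, average_linkage,
                       dynamic_tree_cut, merge_close_modules, module_eigengene,
                       tom_similarity)
from .preprocess import (compute_rpkm, log2_transform, mds_top_sd,
                         remove_batch_effect, tmm_factors)
from .simulate import ModuleSpec, SimulationConfig, generate_dataset

__all__ = [
    "oracle_equivalence",
    "de_calibration",
    "module_recovery",
    "selection_recovery",
    "diffconn_validation",
    "determinism_roundtrip",
]


# ---------------------------------------------------------------------------
# 1. oracle equivalence


def _tom_oracle(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                l_ij = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
                tom[i, j] = (l_ij + A0[i, j]) / (min(k[i], k[j]) + 1.0 - A0[i, j])
    return tom


def _tmm_oracle(counts: np.ndarray, ref_idx: int) -> np.ndarray:
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
                w.append((N[j] - x) / (N[j] * x) + (N[ref_idx] - xr) / (N[ref_idx] * xr))
        M, A, w = map(np.asarray, (M, A, w))
        n = len(M)
        rm = np.empty(n); rm[np.argsort(M, kind="stable")] = np.arange(1, n + 1)
        ra = np.empty(n); ra[np.argsort(A, kind="stable")] = np.arange(1, n + 1)
        keep = ((rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
                & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05)))
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def _upgma_oracle(D: np.ndarray) -> np.ndarray:
    clusters = {i: [i] for i in range(D.shape[0])}
    dist = {(i, j): D[i, j] for i in range(D.shape[0]) for j in range(i + 1, D.shape[0])}
    heights = []
    nxt = D.shape[0]
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k in list(clusters):
            d = np.mean([D[a, b] for a in merged for b in clusters[k]])
            dist[(min(k, nxt), max(k, nxt))] = d
        clusters[nxt] = merged
        nxt += 1
    return np.sort(np.asarray(heights))


def _ks_oracle(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.sort(np.concatenate([x, y]))
    return max(abs(np.mean(x <= v) - np.mean(y <= v)) for v in grid)


def _hypergeom_oracle(overlap: int, N: int, K: int, n: int) -> float:
    from scipy.special import gammaln

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    ks = np.arange(overlap, min(K, n) + 1)
    logs = np.array([logC(K, k) + logC(N - K, n - k) - logC(N, n)
                     for k in ks if n - k <= N - K])
    if logs.size == 0:
        return 0.0
    mx = logs.max()
    return float(np.exp(mx) * np.sum(np.exp(logs - mx)))


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


def oracle_equivalence(seed: int, n_instances: int = 100) -> dict:
    """Max |implementation - oracle| over random small instances of every
    exactly-specified primitive."""
    rng = np.random.default_rng(seed)
    from .datasets import CountDataset

    errs = {k: 0.0 for k in ("tom", "tmm", "upgma", "mds", "ks_d",
                             "hypergeom", "bh")}
    for _ in range(n_instances):
        # TOM
        n = int(rng.integers(4, 14))
        x = rng.uniform(0, 1, (n, n))
        A = (x + x.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(pd.DataFrame(A)).to_numpy()
        errs["tom"] = max(errs["tom"], np.abs(tom - _tom_oracle(A)).max())

        # TMM
        g, s = int(rng.integers(30, 80)), int(rng.integers(3, 7))
        counts = rng.poisson(rng.uniform(5, 200), size=(g, s)) + 1
        gene_ids = pd.Index([f"G{i}" for i in range(g)])
        sample_ids = pd.Index([f"S{i}" for i in range(s)])
        ds = CountDataset(
            counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
            gene_lengths=pd.Series(1000, index=gene_ids),
            samples=pd.DataFrame(
                {"treatment": "UNT", "batch": 1}, index=sample_ids))
        f = tmm_factors(ds, reference_sample="S0")
        errs["tmm"] = max(errs["tmm"], np.abs(
            f.tmm_factors.to_numpy() - _tmm_oracle(counts.astype(float), 0)).max())

        # UPGMA merge heights
        n = int(rng.integers(4, 10))
        x = rng.uniform(0.05, 1.0, (n, n))
        D = (x + x.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = average_linkage(pd.DataFrame(D))
        errs["upgma"] = max(errs["upgma"], np.abs(
            np.sort(Z[:, 2]) - _upgma_oracle(D)).max())

        # classical MDS: reconstructed distances match the original ones
        g, s = 40, int(rng.integers(4, 8))
        vals = rng.normal(0, 1, (g, s))
        expr = ExprMatrix(values=pd.DataFrame(
            vals, index=[f"G{i}" for i in range(g)],
            columns=[f"S{i}" for i in range(s)]), scale="log2CPM")
        coords = mds_top_sd(expr, n_top=g, n_dims=s - 1).to_numpy()
        from scipy.spatial.distance import pdist
        errs["mds"] = max(errs["mds"], np.abs(
            pdist(coords) - pdist(vals.T)).max())

        # KS D
        x = rng.beta(2, 5, int(rng.integers(5, 40)))
        y = rng.beta(2, 2, int(rng.integers(5, 40)))
        d = ks_compare(pd.Series(x), pd.Series(y)).statistic
        errs["ks_d"] = max(errs["ks_d"], abs(d - _ks_oracle(x, y)))

        # hypergeometric upper tail
        from scipy.stats import hypergeom
        N = int(rng.integers(50, 2000))
        K = int(rng.integers(1, N // 2))
        nn = int(rng.integers(1, N // 2))
        ov = int(rng.integers(0, min(K, nn) + 1))
        p = float(hypergeom.sf(ov - 1, N, K, nn))
        errs["hypergeom"] = max(errs["hypergeom"],
                                abs(p - _hypergeom_oracle(ov, N, K, nn)))

        # BH
        p = rng.uniform(size=int(rng.integers(1, 30)))
        errs["bh"] = max(errs["bh"], np.abs(bh_fdr(p) - _bh_oracle(p)).max())

    errs["n_instances"] = n_instances
    return errs


# ---------------------------------------------------------------------------
# 2. DE calibration


def de_calibration(seed: int, n_null_genes: int = 2000,
                   n_power_genes: int = 400) -> dict:
    """Type-I error at nominal 0.05 on a null simulation (n = 20 + 20, 5
    batches) and power at FDR < 0.05 for planted log2FC = 2 at mean count
    100."""
    rng = np.random.default_rng(seed)
    n = 40
    samples = pd.DataFrame(
        {"treatment": ["FBZ"] * 20 + ["UNT"] * 20,
         "batch": [(i % 5) + 1 for i in range(n)]},
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="sample_id"))
    design = build_design(samples, "overall")
    batch_idx = samples["batch"].to_numpy() - 1

    phi = rng.gamma(2.0, 0.05, size=n_null_genes)
    base = rng.normal(np.log(100), 1.0, size=n_null_genes)
    boff = rng.normal(0, 0.1, size=(n_null_genes, 5))
    mu = np.exp(base[:, None] + boff[:, batch_idx])
    r = 1 / phi[:, None]
    null_counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu)),
        index=[f"N{i}" for i in range(n_null_genes)], columns=samples.index)

    phi_p = rng.gamma(2.0, 0.05, size=n_power_genes)
    mu0 = 100 * np.exp(rng.normal(0, 0.2, size=n_power_genes))
    eff = 2.0 * rng.choice([-1.0, 1.0], n_power_genes)
    treated = (samples["treatment"] != "UNT").to_numpy(float)
    mu_p = np.exp(np.log(mu0)[:, None] + np.log(2.0) * np.outer(eff, treated)
                  + rng.normal(0, 0.1, size=(n_power_genes, 5))[:, batch_idx])
    rp = 1 / phi_p[:, None]
    power_counts = pd.DataFrame(
        rng.negative_binomial(rp, rp / (rp + mu_p)),
        index=[f"P{i}" for i in range(n_power_genes)], columns=samples.index)

    counts = pd.concat([null_counts, power_counts])
    # TMM-effective offsets, as in the pipeline: the planted fold changes
    # shift raw library composition between groups, which TMM absorbs
    from .datasets import CountDataset

    ds = CountDataset(
        counts=counts,
        gene_lengths=pd.Series(1000, index=counts.index),
        samples=samples)
    offsets = np.log(tmm_factors(ds).effective_sizes.to_numpy())
    disp = estimate_dispersions(counts, design, offsets)
    fit = fit_nb_glm(counts, design, offsets, disp)
    res = lrt_contrast(fit, counts, offsets, disp, treatment_contrast(design),
                       label="FBZ_vs_UNT")
    res = res.set_index("gene_id")
    null_p = res.loc[null_counts.index, "pvalue"]
    type1 = float((null_p < 0.05).mean())
    power = float((res.loc[power_counts.index, "fdr"] < 0.05).mean())
    return {"type1_error_rate": type1, "power_log2fc2": power,
            "n_null_genes": n_null_genes, "n_power_genes": n_power_genes}


# ---------------------------------------------------------------------------
# 3. module recovery


def module_recovery(seed: int, n_seeds: int = 25, beta: int = 18) -> dict:
    """Planted 2-module design (50 + 50 genes, strength 0.9, 100
    background) embedded in a 2,000-gene transcriptome; network built on
    the 200 design genes from treated samples at the study's soft power."""
    from sklearn.metrics import adjusted_rand_score

    passes, aris = 0, []
    for k in range(n_seeds):
        sim_seed = seed * 10_000 + k
        specs = (ModuleSpec("M1", 50, 0.9), ModuleSpec("M2", 50, 0.9))
        ds, truth = generate_dataset(SimulationConfig(
            n_genes=2000, module_specs=specs, seed=sim_seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            factors = tmm_factors(ds)
            rpkm = log2_transform(compute_rpkm(ds, factors))
            treated = ds.samples["treatment"] != "UNT"
            preserve = pd.DataFrame(
                {"intercept": 1.0, "treated": treated.astype(float)},
                index=ds.sample_ids)
            adj_expr = remove_batch_effect(rpkm, ds.samples["batch"], preserve)
        expr = adj_expr.values.loc[:, treated.to_numpy()]
        rng = np.random.default_rng(sim_seed + 1)
        bg = truth.module_assignment.index[truth.module_assignment == "background"]
        design_genes = sorted(
            list(truth.module_genes("M1")) + list(truth.module_genes("M2"))
            + list(rng.choice(bg, 100, replace=False)))
        expr = expr.loc[design_genes]
        A = adjacency_matrix(expr, beta=beta)
        diss = 1.0 - tom_similarity(A)
        np.fill_diagonal(diss.values, 0.0)
        Z = average_linkage(diss)
        labels = dynamic_tree_cut(Z, A.index, min_module_size=30,
                                  cut_height=0.99 * Z[:, 2].max())
        labels, _ = merge_close_modules(expr.loc[labels.index], labels, 0.15)
        t = truth.module_assignment.loc[labels.index]
        ari = adjusted_rand_score(pd.factorize(t)[0], pd.factorize(labels)[0])
        aris.append(ari)
        n_mod = labels[labels != UNASSIGNED].nunique()
        passes += (ari >= 0.9) and (n_mod == 2)
    return {"pass_rate": passes / n_seeds, "median_ari": float(np.median(aris)),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# 4. selection recovery


def selection_recovery(seed: int, n_seeds: int = 100) -> dict:
    """One trait-linked (target r = 0.5) DE-rich (20%) module among three
    null modules: the |r| > 0.30 & p < 0.10 & DE >= 10% filter must select
    exactly the planted module."""
    hits = 0
    for k in range(n_seeds):
        sim_seed = seed * 10_000 + k
        specs = (
            ModuleSpec("M1", 100, 0.85, 0.5, 0.0, "CL", de_fraction=0.2),
            ModuleSpec("M2", 100, 0.85, 0.0, 0.0, de_fraction=0.0),
            ModuleSpec("M3", 100, 0.85, 0.0, 0.0, de_fraction=0.0),
            ModuleSpec("M4", 100, 0.85, 0.0, 0.0, de_fraction=0.0),
        )
        ds, truth = generate_dataset(SimulationConfig(
            n_genes=1000, module_specs=specs, de_fraction_background=0.02,
            seed=sim_seed))
        treated = ds.samples["treatment"] != "UNT"
        x = np.log2(ds.counts + 1.0)
        labels = truth.module_assignment
        mod_labels = labels[labels != "background"]
        me = module_eigengene(
            x.loc[mod_labels.index, ds.sample_ids[treated]], mod_labels)
        trait_tbl = module_trait_correlations(
            me, ds.traits.loc[ds.sample_ids[treated]])
        design = build_design(ds.samples, "overall")
        offsets = np.log(ds.counts.sum(0).to_numpy())
        disp = estimate_dispersions(ds.counts, design, offsets)
        fit = fit_nb_glm(ds.counts, design, offsets, disp)
        de = lrt_contrast(fit, ds.counts, offsets, disp,
                          treatment_contrast(design), label="FBZ_vs_UNT")
        sel = select_modules(trait_tbl, de, mod_labels)
        hits += set(sel.loc[sel["selected"], "module"]) == {"M1"}
    return {"exact_selection_rate": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# 5. differential connectivity


def diffconn_validation(seed: int, n_seeds: int = 100) -> dict:
    """Planted treated-connectivity gain (module size 250, gain 0.65):
    treated connectivity dominates and the KS comparison is highly
    significant; label swap negates dk exactly."""
    dk_pos = ks_sig = 0
    swap_exact = True
    dks = []
    for k in range(n_seeds):
        sim_seed = seed * 10_000 + k
        specs = (ModuleSpec("M1", 250, 0.9, 0.0, 0.65),)
        ds, truth = generate_dataset(SimulationConfig(
            n_genes=4000, module_specs=specs, seed=sim_seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            factors = tmm_factors(ds)
            rpkm = log2_transform(compute_rpkm(ds, factors))
            treated = ds.samples["treatment"] != "UNT"
            preserve = pd.DataFrame(
                {"intercept": 1.0, "treated": treated.astype(float)},
                index=ds.sample_ids)
            expr = remove_batch_effect(rpkm, ds.samples["batch"], preserve).values
        genes = truth.module_genes("M1")
        kt = scaled_connectivity(expr.loc[:, treated.to_numpy()], genes, 18)
        ku = scaled_connectivity(expr.loc[:, (~treated).to_numpy()], genes, 18)
        dk = kt - ku
        dks.append(dk.mean())
        dk_pos += dk.mean() > 0
        ks = ks_compare(kt, ku)
        ks_sig += ks.pvalue < 0.001
        swap = ks_compare(ku, kt)
        swap_exact &= (swap.statistic == ks.statistic)
        swap_exact &= np.allclose((ku - kt).to_numpy(), -dk.to_numpy(), atol=0)
    return {
        "mean_dk_positive_rate": dk_pos / n_seeds,
        "ks_p_below_0.001_rate": ks_sig / n_seeds,
        "mean_delta_k": float(np.mean(dks)),
        "label_swap_antisymmetric": bool(swap_exact),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 6. determinism & round trip


def determinism_roundtrip(seed: int, tmp_dir) -> dict:
    """Byte-identical rerun of the full arm pipeline under a fixed seed,
    plus lossless TSV round trips of the input bundle."""
    from pathlib import Path

    from . import io as hio
    from .pipeline import RunConfig, run_arm
    from .simulate import write_dataset

    tmp_dir = Path(tmp_dir)
    specs = (
        ModuleSpec("M1", 80, 0.9, 0.5, 0.65, "CL", de_fraction=0.25),
        ModuleSpec("M2", 50, 0.9, 0.0, 0.0, de_fraction=0.0),
    )
    cfg = SimulationConfig(n_genes=1000, module_specs=specs, seed=seed)
    ds, truth = generate_dataset(cfg)
    data_dir = tmp_dir / "data"
    write_dataset(ds, truth, data_dir)
    back = hio.read_dataset(data_dir)
    roundtrip_ok = (
        ds.counts.equals(back.counts)
        and ds.gene_lengths.equals(back.gene_lengths)
        and ds.samples.equals(back.samples)
        and np.allclose(ds.traits.to_numpy(), back.traits.to_numpy(),
                        equal_nan=True)
    )

    out = tmp_dir / "run"
    rc = RunConfig(data_dir=str(data_dir), arm="FBZ", out_dir=str(out),
                   beta=12, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_arm(rc)
        first = {f.name: f.read_bytes() for f in out.iterdir()
                 if f.name != "summary.json"}
        run_arm(rc)
    identical = all(
        (out / name).read_bytes() == blob for name, blob in first.items())
    return {"roundtrip_lossless": bool(roundtrip_ok),
            "rerun_byte_identical": bool(identical)}
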