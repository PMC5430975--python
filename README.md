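# hepanet

Weighted gene co-expression network analysis of drug-metabolism liver
transcriptomes, for researchers studying how individual variation in
hepatic gene expression relates to pharmacokinetic (PK) phenotypes.

The package implements the full integrated workflow of a
treated-vs-untreated PK RNA-seq study (two drug arms — fenbendazole,
FBZ, and flunixin meglumine, FLU — sharing one untreated group, ~20
animals per group across 5 batches), together with a synthetic-data
generator that plants every feature the workflow is supposed to find, so
each stage is testable offline against known truth.

## The method

1. **Filtering & normalization.** Genes with CPM > 1 in at least 5
   samples (jointly across all samples) are kept; library composition is
   corrected by trimmed-mean-of-M-values (TMM) factors; expression is
   expressed as CPM for count modeling and RPKM for cross-gene network
   work; log2(x+1) throughout; sample structure is inspected by
   classical metric MDS on the 500 highest-SD genes.
2. **Differential expression.** Per gene, a negative-binomial GLM with
   log link and TMM-effective offsets: overall treated-vs-untreated
   contrasts per arm plus the breed/sex interaction contrasts
   (T_A − U_A) − (T_B − U_B), batch-adjusted. Dispersions are moment
   estimates shrunk toward a trimmed-mean common value; tests are
   likelihood-ratio χ²(1); multiplicity is controlled by
   Benjamini–Hochberg FDR (< 0.05).
3. **Network construction.** Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β`
   with β chosen by the scale-free topology criterion (the study regime
   is β = 18); topological overlap (TOM) dissimilarity; average-linkage
   clustering; modules as dendrogram branches (static cut, minimum size
   30, color-style names, "grey" unassigned); module eigengenes (first
   PC) merged when r > 0.85.
4. **Module–trait integration.** Eigengene vs PK-parameter Pearson
   correlations (treated animals only — untreated have no PK record);
   a module is carried forward when |r| > 0.30, p < 0.10 and ≥ 10% of
   its genes are DE at FDR < 0.05; module membership kME is reported for
   every gene × module pair.
5. **Differential connectivity.** Within each selected module, scaled
   connectivity k ∈ [0, 1] (row sum of adjacency ÷ network max) is
   computed separately in treated and untreated samples at the same β;
   Δk = k_treated − k_untreated, |Δk| > 0.6 flags hub candidates; the
   two connectivity distributions are compared by a two-sample
   Kolmogorov–Smirnov test.
6. **Enrichment.** Hypergeometric upper-tail (one-sided Fisher) tests of
   each selected module against the expressed-gene background, BH FDR
   per module.

## Worked example

The three analysis drivers simulate the two-arm study (4,000 genes, four
planted PK-linked modules per arm), run the complete per-arm pipeline,
and check every finding against the planted truth:

```bash
python analysis/01_simulate_study.py
python analysis/02_run_arms.py
python analysis/03_summarize_findings.py
```

The second step prints, per arm:

```
[FBZ] kept 4000 genes; beta=18 (scale-free R^2 0.67); 4 modules; 281 DE genes;
      selected ['blue', 'brown', 'turquoise', 'yellow']; 32 hub genes; 4 enriched terms
[FLU] kept 4000 genes; beta=18 (scale-free R^2 0.84); 4 modules; 273 DE genes;
      selected ['blue', 'brown', 'turquoise', 'yellow']; 38 hub genes; 4 enriched terms
```

and the summary step reports each selected module, e.g. for FBZ:

```
module     n_genes best_trait    r      p     de_fraction planted_overlap ks_pvalue
turquoise  259     CL         -0.461  0.041   0.154        250/250        3.7e-08
brown      123     T12        -0.447  0.048   0.154        120/120        4.8e-06
yellow      85     MRT        -0.417  0.067   0.165         80/80         9.3e-14
```

Reading: each detected module recovers its planted module essentially
gene-for-gene; eigengene–trait correlations sit in the |r| 0.41–0.57
band with p < 0.10; every module's genes are more interconnected in
treated than untreated animals (mean k 0.44 vs 0.35 for turquoise, KS
p ≤ 7e-6 everywhere), and the planted annotation term is the top
enrichment hit in all 8 selected modules across both arms. A `hepanet`
CLI exposes the same stages (`hepanet simulate`, `hepanet run-all`, …).

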