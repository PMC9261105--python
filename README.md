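# coexnet

Weighted gene co-expression network analysis for clinical transcriptomic
cohorts: build co-expression modules from a normalized expression matrix,
relate module eigengenes to clinical scales under covariate adjustment,
select hub genes, quantify module robustness by subsampling, and validate
modules against external partitions and gene-set annotations.

The package targets the typical blood-transcriptome cohort study in
psychiatry and related fields — on the order of 15,000–20,000 genes
measured in ~90 participants, with ~10 clinical scales (e.g., CGI, GAF,
FAST, PANSS subscales, YMRS, MADRS, PAS) and covariates such as sex, age,
age at onset, ethnicity, and blood cell composition. A synthetic-study
generator with planted ground truth makes every stage testable without any
external data.

## The method

Starting from a genes × samples matrix `X` (log-scale, normalized):

1. **Sample QC.** Pairwise sample distances give a sample adjacency
   `A_ij = 1 − d_ij / max(d)`; connectivity `k_i = Σ_{j≠i} A_ij` is
   standardized to `Z_k`, and samples with `Z_k < −5` are removed.
2. **Network.** Pearson correlations `r_ij` between all gene pairs are
   soft-thresholded to a weighted adjacency `a_ij = |r_ij|^β` (β = 6 by
   default; signed variant `((1+r)/2)^β` available). The topological
   overlap matrix

   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, with
   `l_ij = Σ_u a_iu a_uj`,

   measures shared neighborhood, and `1 − TOM` feeds average-linkage
   hierarchical clustering.
3. **Modules.** A dynamic (variable-height) cut of the dendrogram yields
   modules of at least 30 genes; unassigned genes are labeled **grey**.
   Each module is summarized by its **eigengene** (ME) — the first
   principal component of the standardized module submatrix — and modules
   whose eigengenes correlate above 0.75 (merge cut height 0.25) are
   merged. Modules get canonical color labels in decreasing size order.
4. **Association.** Each ME is related to each clinical trait by Pearson
   **partial correlation** (both residualized on the covariates), with
   percentile bootstrap confidence intervals (1000 resamples) and
   Benjamini–Hochberg FDR across the whole module × trait family. Gene
   significance `GS = |cor(x_g, trait)|` and module membership
   `MM = cor(x_g, ME)` define **hub genes** (`|MM| > 0.8`, `GS > 0.3`);
   significant modules are clustered by their trait-correlation profiles
   and hub genes are pooled per cluster.
5. **Validation.** Module stability = the percentage of 50 subsampling
   reruns (80% of samples) in which a gene returns to its module,
   averaged per module; external validation and hub-set
   over-representation use the upper-tail hypergeometric test with
   multiplicity correction.

## Worked example

```python
from coexnet import (SyntheticConfig, TraitSpec, simulate_study,
                     CoexpressionNetwork, ModuleTraitModel)

traits = [TraitSpec("GAF", 0, 0.5), TraitSpec("PANSS_total", 1, -0.5),
          TraitSpec("FAST", 2, 0.4), TraitSpec("MADRS"), TraitSpec("YMRS")]
cfg = SyntheticConfig(module_sizes=[150, 120, 100], n_genes=500,
                      n_samples=90, traits=traits, seed=1)
study = simulate_study(cfg)

net = CoexpressionNetwork(study.expression).fit()
print(net.summary())

res = ModuleTraitModel(net, study.traits, study.covariates).fit(
    bootstrap_B=500, seed=1)
print(res.summary())
```

prints

```
Weighted co-expression network
==============================================
genes: 500   samples: 90   outliers removed: 0
power: 6 (unsigned)   min module size: 30   merge height: 0.25
modules: 3   unassigned (grey): 128

module sizes:
  turquoise          152
  blue               120
  brown              100

Module eigengene - trait association
==============================================
modules: 3   traits: 5   FDR alpha: 0.05
significant cells: 4   significant modules: MEblue, MEbrown, MEturquoise
raw-p cutoff at the BH decision: 0.00915

partial correlations (r):
trait         FAST    GAF  MADRS  PANSS_total   YMRS
module                                              
MEblue      -0.000 -0.013 -0.056       -0.490  0.070
MEbrown      0.333 -0.080 -0.011        0.013  0.150
MEturquoise  0.001  0.412  0.280        0.161  0.016
```

The three planted modules are recovered almost exactly (152/120/100 genes
against the planted 150/120/100; the 150 background noise genes land in
grey plus small spillover). Each coupled module–trait cell is significant
with the planted sign and magnitude near its coupling strength (e.g.,
`cor(MEturquoise, GAF) = 0.41` for a planted `γ = 0.5` at n = 90), while
uncoupled cells stay near zero. The reported raw-p cutoff is the
data-dependent threshold implied by the BH decision at FDR 0.05.

## Command line

```sh
coexnet simulate --out study/ --seed 3          # synthetic cohort + truth.json
coexnet run --config pipeline.yaml              # full pipeline -> result bundle
coexnet qc|network|associate|hubs|stability|overlap|enrich ...
```

`run` writes module assignments, eigengenes, module–trait tables with
bootstrap CIs, GS–MM tests, hub sets per module cluster, stability
reports, overlap/enrichment tables, and a `manifest.json` with SHA-256
hashes of every artifact (reruns with the same config and seed are
byte-identical).

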