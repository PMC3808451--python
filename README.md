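# pycape

Directed genetic interaction networks from the combined analysis of
pleiotropy and epistasis (CAPE), for multi-phenotype cross data.

## The problem

In a segregating population (a backcross, an intercross, a collection of
engineered perturbations) two loci often interact: their joint effect on a
quantitative trait deviates from the sum of their single-locus effects.
Classical epistasis scans detect this deviation one phenotype at a time,
but the resulting interaction term is symmetric — it says *that* two loci
interact, not *which* locus is modifying the other. When several related
phenotypes have been measured, pleiotropy supplies the missing
information: a model in which locus A rescales the effect of locus B must
fit **every** phenotype simultaneously, and phenotypes that respond to A
but not to B (or vice versa) break the symmetry.

`pycape` implements this strategy for users with R/qtl-format cross data
and two or more quantitative phenotypes: geneticists mapping metabolic,
behavioral or expression traits who want interpretable, directed
hypotheses about which variants suppress or enhance which.

## The model

1. **Eigentraits.** Phenotypes are rank-normalized and decomposed by
   singular value decomposition, `P = U Σ Vᵀ`. The orthonormal columns of
   `U` are the *eigentraits* (ETs); by default the first two are analyzed
   (up to 12 are supported).

2. **Pair scan.** For every testable marker pair and each selected ET *j*,
   ordinary least squares fits

   `ET_j ~ β₀ + γ·covariates + β₁⁽ʲ⁾x₁ + β₂⁽ʲ⁾x₂ + β₁₂⁽ʲ⁾x₁x₂`

   Pairs whose four two-locus genotype classes are not each observed at
   least 6 times are excluded (linkage disequilibrium makes the
   interaction term unidentifiable).

3. **Reparametrization.** The per-ET interaction coefficients are replaced
   by two phenotype-independent directed influences `(m₁₂, m₂₁)` through

   `β₁₂⁽ʲ⁾ = m₁₂ β₂⁽ʲ⁾ + m₂₁ β₁⁽ʲ⁾  for every ET j`

   — the source variant rescales the target's effective allele dose.
   For two ETs the system is solved exactly (residuals of the pairwise fit
   are unchanged); for more ETs by least squares. Standard errors are
   propagated to first order, giving standardized effects `z = m/SE`
   (negative = suppression, positive = enhancement).

4. **Significance.** ET rows are permuted against the fixed genotypes; all
   standardized effects from all permutations are pooled into one null for
   variant→variant influences and one for variant→phenotype (main)
   effects. Two-sided add-one empirical p-values are corrected by Holm,
   Benjamini–Hochberg FDR (default, level 0.01) or local FDR.

5. **Network.** Significant effects fill an asymmetric adjacency matrix —
   source markers in rows, target markers plus phenotypes in columns —
   exportable as labelled CSV, edge list, or GraphML.

## Worked example

A synthetic backcross (300 individuals, two chromosomes of four markers)
with one planted influence: marker `M1_3` fully suppresses marker `M2_3`
(`m = −1`). `M1_3` affects both phenotypes, `M2_3` only the first — the
configuration that lets the method orient the edge.

```python
import pycape

cross, truth = pycape.make_fixture("one_directed_edge", 100)
cfg = pycape.RunConfig(n_perm=50, method="fdr", level=0.05, seed=1000,
                       output_dir="demo_out")
manifest = pycape.run_full_analysis(cfg, cross=cross)
```

`demo_out/et_report.csv` — ET1 carries the shared signal (66% of
variance, equal positive loadings), ET2 the divergence between the
phenotypes:

```
 et  variance_fraction  loading_phen1  loading_phen2
  1           0.664868       0.707107       0.707107
  2           0.335132       0.707107      -0.707107
```

`demo_out/influences.csv` for the planted pair — the influence of `M1_3`
on `M2_3` is recovered near its generative value of −1, with a strongly
standardized effect in the planted direction only:

```
marker_1 marker_2       m12      m21   se_m12   se_m21     z_m12    z_m21   status
    M1_3     M2_3 -0.948565 0.180642 0.209984 0.167119 -4.517329 1.080918 resolved
```

`demo_out/edges.csv` — the significant network at FDR 0.05. The planted
suppressive edge is present with the correct orientation and a negative
sign, together with its positive main effects on both phenotypes (the two
extra marker edges are neighbors linked to the true pair at 30 cM):

```
source target    weight sign              kind
  M1_2   M2_3 -3.226428    -   variant_variant
  M1_3   M2_2 -3.636197    -   variant_variant
  M1_3   M2_3 -4.517329    -   variant_variant
  M1_3  phen1  0.860914    + variant_phenotype
  M1_3  phen2  0.905851    + variant_phenotype
```

The same analysis runs from the shell:

```bash
cape simulate one_directed_edge --seed 100 --out fix.csv
cape run fix.csv --n-perm 50 --method fdr --level 0.05 --seed 1000 --out demo_out
cape decompose fix.csv --out ets.csv     # ET report only
cape pairs fix.csv --out pair_filter.csv # LD filter report only
```

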