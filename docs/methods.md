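# Methods

## Model and assumptions

`pycape` infers directed variant-to-variant influences from multi-phenotype
cross data. The generative picture is that the presence of a source allele
rescales the *effective dose* of a target allele: with dosages
`x_s, x_t ∈ [0, 1]`, the target acts with dose `x_t (1 + m x_s)`, where
`m < 0` is suppression (`m = −1` complete suppression) and `m > 0`
enhancement. Under this model the ordinary two-locus regression of any
linear phenotype combination on `(x₁, x₂, x₁x₂)` satisfies the identity
`β₁₂ = m₁₂ β₂ + m₂₁ β₁`, which is what the reparametrization inverts.

Assumptions that matter in practice:

- **Biallelic 0/1 (or 0/0.5/1) dosage coding.** Backcross data are 0/1;
  intercross heterozygotes enter at half dose. Multi-allele encodings and
  haplotype probabilities are out of scope.
- **Moderate pleiotropy.** Orientation of an influence is identified only
  when the two loci load differently on at least two eigentraits; traits
  with pairwise correlations of roughly 0.4–0.8 are the useful regime.
  Perfectly correlated traits make the two-ET system singular (such pairs
  are reported `unresolved` rather than forced).
- **Linear, homoscedastic trait model within genotype classes**, made more
  plausible by rank-normalizing each phenotype first.
- **No population structure / relatedness corrections.** Samples are
  treated as exchangeable, which is what the row-permutation null assumes.

## Pipeline and parameter defaults

| stage | parameter | default | rationale |
|---|---|---|---|
| input | genotype code preset | `backcross` {A:0, H:1} | required, explicit; `intercross` {A:0, H:0.5, B:1} also provided |
| input | missing codes | `-`, `NA`, empty | common R/qtl conventions |
| normalization | rank-Z (Blom offset 3/8), then z-score (ddof 1) | — | robust for skewed metabolic traits; isolated behind a transform record so alternatives can be configured |
| decomposition | number of ETs | 2 (2–12 allowed) | the first two ETs typically carry the shared signal and the leading divergence; each extra ET adds a constraint the single pairwise model must fit and tends to dilute significance |
| pair filter | min two-locus class count | 6 | every one of the four classes needs ≥ 6 observations, which also guarantees the interaction term is estimable; dosages are binarized (≥ 0.5 → 1) for this filter only, never for regression |
| reparametrization | condition tolerance | 1e8 (singular-value ratio of the N×2 system) | near-parallel main-effect vectors (degenerate pleiotropy) make direction unidentifiable; such pairs are `unresolved` |
| permutations | n_perm | 100 | pooling across pairs makes ~100 permutations give pool sizes of 10⁵–10⁶ |
| significance | method, level | BH FDR, 0.01 | conservative default for genome-wide interaction claims |

Covariates (sex, maternal environment, treatment) are promoted to
pseudo-markers on chromosome "0": min–max rescaled to [0, 1] and treated
as ordinary loci everywhere, including as pair-candidates, so
covariate-by-marker interactions are tested. They are **not** added as
additive regression covariates to the pair scan (a pair member may never
simultaneously be a regression covariate); only user-selected strong
main-effect markers (via `select_marker_covariates`) play that role.

Markers fully redundant with the preceding retained marker on the same
chromosome (identical on jointly observed entries) are dropped before the
scan; exact equality is required, as "full redundancy" is the criterion,
not near-redundancy, and only adjacent comparisons are made.

## Error propagation

The covariance of `(m₁₂, m₂₁)` is obtained by the first-order delta
method. Differentiating the normal equations `(MᵀM)m = Mᵀb` gives the
exact Jacobian `dm = (MᵀM)⁻¹(dMᵀ r − Mᵀ dM m + Mᵀ db)` with
`r = b − Mm` (zero in the square two-ET case); per-ET coefficient
covariances come from the OLS fits, and cross-ET blocks are set to zero —
an approximation justified by the orthogonality of the eigentraits and
the separate regressions. The analytic Jacobian is verified against
central differences in the tests, and the propagated SEs against
Monte-Carlo resampling of the coefficients. The Monte-Carlo agreement
check is run in the small-noise regime (coefficient SEs ≈ 0.5% of the
coefficient scale), where the linearization is the well-defined target;
the deviation grows quadratically with the noise scale, which is
first-order truncation error rather than a propagation defect. At
realistic noise the first-order SE is still the reported quantity.

## The permutation null and its shape

Null distributions are built by permuting the ET matrix rows (all ET
columns jointly, preserving their correlation) against fixed genotypes
(preserving linkage), re-running the pair scan and reparametrization, and
pooling all standardized effects across permutations — separately for
variant→variant and variant→phenotype statistics. Per-permutation seeds
are derived from one master seed, so runs are bit-reproducible.

A property worth knowing: the null distribution of the influence z-scores
is **left-skewed**, not symmetric (median < 0; in a direct simulation
roughly 70% of null z's are negative). With 0/1 dosage coding the
interaction column `x₁x₂` is positively correlated with the main-effect
columns, so OLS makes `β₁₂` negatively correlated with `β₁, β₂`, and the
ratio-like influence estimate inherits a negative bias. This is precisely
why significance is assessed against the permutation null rather than a
normal reference; two-sided `|z|` empirical p-values remain uniform under
the null (verified by simulation), but a uniformly negative tint among
borderline interaction estimates should not, by itself, be read as
biology. Empirical p-values use the add-one convention
`p = (1 + #{|null| ≥ |z|}) / (1 + pool)`, so the attainable floor is
`1/(pool+1)` and is reported in the run manifest.

Local FDR is concretized as the kernel-density ratio `π₀ f₀(z)/f(z)` with
`π₀ = 1` (conservative), both densities evaluated with one shared
bandwidth (Silverman's rule on the pooled null), clipped to [0, 1].

## Main-effect consolidation

A marker's main effect is re-estimated in every pair that contains it.
Per selected ET the entry with the **largest** empirical p across all
pairings is kept, so an effect is claimed only if it survives
conditioning on every tested partner — a partner that fully absorbs the
effect drives the consolidated p toward 1, which is the behavior needed
to recognize complete suppression. The marker-level p is the smallest of
the per-ET conservative p's, and the chosen per-ET coefficient vector is
back-projected (`Σᵢ βᵢ σᵢ V[·,i]`) to phenotype space for signed
reporting. Marker→phenotype and marker→marker families are corrected
separately but thresholded at the same level.

## What the synthetic data emulates — and what it does not

`simdata` generates backcross genotypes marker-by-marker with the Haldane
(no-interference) map function, `r = ½(1 − e^{−2d/100})` for spacing `d`
cM, and phenotypes from known main effects on influence-modified doses, a
shared latent trait (the pleiotropy knob) and Gaussian noise. It emulates
allele frequencies near ½, map-driven LD, moderate trait correlations and
planted directed influences; it does **not** emulate segregation
distortion, genotyping error, dominance, crossover interference,
non-Gaussian trait noise, or family structure. Passing tests on these
fixtures therefore demonstrate correctness of the algorithmic chain and
calibration under the stated model, not robustness to those features of
real data.

Scenario scales (chosen as the package's own validation sizes):

- `null`: 200 individuals, 20 unlinked markers, 2 correlated phenotypes,
  no genetic effect — type-I error and p-uniformity checks.
- `one_directed_edge`: 300 individuals, two chromosomes × 4 markers at
  30 cM, main effects 1.3 (trait SD units) with the source affecting both
  phenotypes and the target only one, influence `m = −1`. Effect sizes
  were calibrated once so the full pipeline at FDR 0.05 recovers the
  planted orientation in ≥ 80% of independent seeds (observed 19/20 at
  calibration, 20/20 in the validation run).
- `hub`: one source suppressing three targets — qualitative network-shape
  checks.
- `example_like`: 203 individuals, 80 markers on 8 chromosomes at 10 cM,
  three phenotypes with pairwise correlations near 0.6 and one binary
  covariate — a realistic end-to-end scale (≈ 3200 testable pairs).

## Numerical choices and degenerate inputs

- SVD sign convention: each right singular vector's largest-magnitude
  loading is positive, fixing signs across linear-algebra backends.
- Rows with any missing phenotype are dropped before the SVD (reported in
  the basis); per-pair genotype missingness is handled by complete-case
  fitting within each pair's regression.
- Rank-deficient designs (e.g. a marker paired with its duplicate, or a
  marker that is also a covariate) are flagged `unresolved`, never fatal.
- Zero propagated SE (noiseless fits) marks an estimate `degenerate` and
  excludes it from testing instead of producing infinite z.
- `TruthModel.noise_sd` may be exactly 0: the noiseless limit is the
  regime in which the pair-scan identity `β₁₂ = m·β_target` holds to
  machine precision and is used as a consistency check.
- All stochastic steps derive their seeds from a single master seed
  (sub-seeds kept below 2³¹); two runs with the same configuration and
  seed produce bit-identical outputs (manifest timing fields aside).

## Known limitations

- Two-locus interactions only; no three-way terms.
- Orientation requires differential pleiotropy; interactions expressed
  identically in all measured traits remain direction-ambiguous
  (`unresolved` or weakly oriented), and redundant epistasis detectable
  by single-trait methods may be missed.
- The pooled null assumes standardized effects are exchangeable across
  pairs; strongly heterogeneous allele frequencies could violate this
  (the pooled-vs-per-parameter agreement is verified at the simulated
  scales).
- GWAS-scale marker counts, kinship corrections and >2-allele encodings
  are out of scope.
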