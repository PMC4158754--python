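# Methods

This note records the statistical model, the estimation machinery, the
numerical conventions, and the design choices made where more than one
reasonable option existed. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Mixed model and likelihood

The trait model is `y = F b + Σ_m g^m + e` with `g^m ~ N(0, σ²_m K^m)` and
`e ~ N(0, σ²_e I)`. Each genomic similarity matrix is an average allelic
correlation, `K^m = X^m X^m′ / p_m`, over the normalized genotypes of its
SNP class. Estimation maximizes the restricted log-likelihood

    l = −½ [ log|V| + log|F′V⁻¹F| + y′Py ],
    V = Σ_m σ²_m K^m + σ²_e I,
    P = V⁻¹ − V⁻¹F(F′V⁻¹F)⁻¹F′V⁻¹.

The additive constant −((n−c)/2)·log 2π is omitted everywhere; only
likelihood differences are ever interpreted, and the convention is fixed
across both back ends, so the omission is immaterial. An intercept is always
included in `F` even when the caller supplies no covariates.

## AI-REML

Updates are Newton steps using the average-information matrix
`AI_{mk} = ½ y′P K^m P K^k P y` and gradient
`d_m = −½ [tr(P K^m) − y′P K^m P y]`, with:

* **Step-halving.** A proposed step is halved (up to 30 times) until the
  restricted log-likelihood does not decrease and V stays positive
  definite; accepted iterations therefore form a monotone sequence. If no
  fraction of the step improves, the fit stops where it is and is flagged
  unconverged.
* **Singular AI fallback.** If the AI matrix cannot be solved (e.g. two
  identical components make it singular), a minimum-norm least-squares step
  is used, and failing that an expectation-maximization step
  `Δσ²_m = σ⁴_m (y′PK^mPy − tr(PK^m)) / n`.
* **Constraints.** Proposals below zero are clamped to zero for that
  iteration (`constraint_floor = 0`); the noise variance is floored at a
  tiny positive multiple of var(y).
* **Permanent zeroing.** A component whose variance share —
  `σ²_m · mean diag(K^m)` over the total including noise — stays below
  0.01% (`1e-4`) for two consecutive iterations is fixed at zero for all
  later iterations. This is what lets the model carry very many regions.
* **Initialization.** Genetic components start at an equal split of half
  the phenotypic variance, `σ²_m = 0.5·var(y)/(M·mean diag K^m)`, noise at
  `0.5·var(y)`. The symmetric start avoids ordering bias among classes.
* **Convergence.** Absolute log-likelihood change below `1e-4` (the
  `loglik_tol` option; tests that need sharp optima pass a tighter value).

Two back ends drive identical iterations. The dense engine factorizes V
directly (Cholesky) and is valid for any component structure. The low-rank
engine applies when at most one component has full rank and the remaining
classes together hold fewer SNPs than individuals: with the full-rank
`K¹ = UEU′` eigendecomposed once, everything is rotated into the U basis
where `A = σ²₁E + σ²_e I` is diagonal, and the regional classes enter
through the Woodbury identity
`V⁻¹ = A⁻¹ − A⁻¹Z(D⁻¹ + Z′A⁻¹Z)⁻¹Z′A⁻¹` with `Z` the concatenated regional
genotype blocks scaled by `1/√p_m` and `D` diagonal. No n×n product occurs
after the one-time eigendecomposition; zeroed components simply drop their
columns from Z. Both engines compute the same gradients and AI matrices, so
their estimates agree to numerical precision (verified to 1e-6 in the
acceptance suite).

## Genotype handling

* PLINK 1 binary filesets are read and written natively (SNP-major layout,
  two-bit codes 00/01/10/11 = hom-allele1 / missing / het / hom-allele2,
  first sample in the low-order bits).
* QC filters — minor allele frequency, call rate, and a two-sided exact
  conditional Hardy–Weinberg test (full enumeration over heterozygote
  counts, summing configurations no more probable than observed) — are all
  evaluated on the input matrix, not sequentially.
* Normalization centres by `2f` and scales by `√(2f(1−f))` with in-sample
  frequencies ("standardized kinship" convention); missing calls are
  mean-imputed, i.e. contribute 0 on the normalized scale. Monomorphic SNPs
  are rejected rather than silently dropped.
* In cross-validation every training-derived quantity — covariate
  regression, allele frequencies, normalization parameters, window tests,
  region discovery, REML, effect estimation — is recomputed from training
  samples only, and the training frequencies are frozen into the prediction
  model used on held-out individuals.
* Case/control traits are handled on the observed 0/1 scale after covariate
  residualization; no liability-scale transformation is applied, since
  ranking-based comparison of methods is unaffected by the monotone map
  between scales.

## Prediction

Per-SNP effects are back-solved as `β^m = (σ̂²_m/p_m)(X^m)′ V̂⁻¹(y − F b̂)`,
which never inverts a (typically singular) regional kinship matrix and
reproduces the fitted training random effects exactly
(`X^m β^m = ĝ^m`). The kinship route — conditional expectation
`ĝ^m_T = K^m_TS (K^m_SS + ridge)⁻¹ ĝ^m_S` with ridge `1e-8 ×` mean diagonal —
is retained for components without SNP-level representation and as an
independent cross-check; the two routes agree to 1e-6 whenever both apply.
Allele flips in new data (allele1/allele2 swapped relative to the model)
are resolved by reflecting the genotype code; any other allele mismatch is
an error.

## Adaptive region discovery

Windows of 75 kb at a 37.5 kb step (defaults) tile each chromosome from its
first SNP; empty windows are dropped. Each window is tested for effect-size
variance distinct from the background:

* **Exact test** (structured cohorts): l₀ maximizes the likelihood with the
  single all-SNP GSM, l₁ with the window GSM and its complement
  (recovered algebraically from the all-SNP matrix). The statistic
  2(l₁−l₀), floored at 0, is referred to χ²(1), although
  the non-negativity constraint makes this conservative (the boundary null
  is a ½χ²₀+½χ²₁ mixture). Because the tied-variance point reproduces the
  single-GSM model, l₁ ≥ l₀ is enforced by construction. The all-SNP null
  fit is shared across windows.
* **Fast test** (predominantly unrelated cohorts): the window's
  contribution is tested against a noise-only model in the spectral basis
  of the window's Gram matrix after projecting out the fixed effects — cost
  O(n·p_w²), no n×n algebra. The background term is dropped because with
  low relatedness the all-SNP GSM is near the identity. The window variance
  is profiled over an *unconstrained* range (keeping V positive definite),
  which removes the boundary problem: the statistic is asymptotically χ²(1)
  and the p-values are calibrated rather than conservative (type-I error at
  5% verified within the binomial band in the acceptance suite). The fast
  test is our concrete reading of the efficient-screen idea; the literature
  it descends from does not fix a unique algorithm.

Mode dispatch uses the 97.5% quantile of off-diagonal kinship (threshold
0.05 by default): below it, individuals are treated as unrelated. Seeds are
windows with p below 10⁻⁶ (Bonferroni-motivated; a relaxed 5×10⁻⁶ suits
sparser genomes); clusters grow through transitively connected neighbours —
windows whose base-pair intervals overlap or abut on the same chromosome —
below 10⁻². Local regions are the SNP unions of seeded clusters; every
other SNP joins the single background region, and the partition is disjoint
and exhaustive by construction. Window testing parallelizes over a worker
pool with results invariant to worker count.

## Synthetic data

The generator emulates the two cohort archetypes used throughout:

* **Unrelated cohort** (GWAS-like): two independent haplotypes per
  individual from a Gaussian-copula AR(1) model — per-SNP frequencies
  Uniform(0.05, 0.5), latent autocorrelation 0.2 within chromosomes, SNP
  spacing 9,375 bp (eight SNPs per 75 kb, the density of the emulated GWAS
  panels), two chromosomes by default.
* **Family cohort** (heterogeneous-stock-like): equal-sized sibships whose
  parents carry haplotypes drawn from a pool of 16 founder haplotypes;
  children inherit one parental haplotype per chromosome. This yields sib
  kinship near 0.5 and elevated between-family kinship, widening the
  off-diagonal kinship distribution the way structured panels do. SNPs
  monomorphic across the founder pool are re-seeded with one variant
  haplotype so the panel stays polymorphic.

Phenotypes allocate heritability across five contiguous, near-equal SNP
regions under three canonical designs — equal shares, shares proportional
to 1:2:3:4:5, and all heritability in the last region — with 20 causal SNPs
per contributing region (or all SNPs). Regional genetic contributions are
rescaled so realized in-sample variance shares hit the target allocation
*exactly*, and noise is rescaled to 1−h²; this makes recovery checks sharp
rather than blurred by effect-sampling noise. The breeding value is the sum
of the genetic contributions.

What the generator does **not** emulate: real LD block structure,
recombination maps, allele-frequency spectra, or genotyping error. Passing
tests therefore demonstrate correctness of the machinery and the *relative*
behaviour of methods under controlled architectures, not absolute
prediction accuracies on any real cohort — the simulation checks compare
methods at the level of orderings and gaps, not absolute values.

## Problem sizes

The simulation-pattern checks run at n = 1200 individuals × 2000 SNPs with
20 repetitions and a 5:1 train/test split; heritability recovery at
n = 2000 × 1000; window-test calibration with 500 null traits at n = 1000;
adaptive-behaviour checks over 50 seeds at n = 1000–1500 × 1000. These
sizes were chosen so each check resolves its target pattern comfortably
while the whole suite stays desk-scale.

## Known limitations

* The χ²(1) reference for the exact window test is conservative at the
  boundary; the adaptive seed threshold compensates in practice but small
  effects near the threshold are found less often in exact mode than in
  fast mode.
* Effect back-solving requires SNP-level representation; purely
  pedigree-style covariance components can be fitted but only predicted via
  the kinship route.
* No dosage/VCF input, no X-chromosome handling, no imputation, no
  dominance or epistasis covariances, and no liability-scale heritability
  conversion.
* LD pruning and risk-score construction use greedy marginal statistics;
  they are comparators, not the method of interest.
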