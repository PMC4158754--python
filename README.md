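# multiblup

Genomic prediction of complex traits with **multiple SNP-class random
effects**, plus an adaptive procedure that discovers the SNP classes itself.

Standard genomic BLUP (GBLUP) predicts a trait from genome-wide SNPs with a
single random effect whose correlation structure is a kinship (genomic
similarity) matrix averaged over all SNPs. That model implicitly assumes
every SNP effect comes from one common Gaussian distribution — a poor fit
for traits where a few regions (the MHC in autoimmune disease, a major QTL
in a breeding population) carry far more signal per SNP than the polygenic
background. This package generalizes the model to one genomic random effect
per SNP class, so classes with large effect-size variance can contribute
strongly to prediction without being shrunk toward the genome-wide average.

It is aimed at statistical geneticists and breeders who want to go beyond
single-kinship GBLUP: supply SNP classes from annotation (genes, pathways,
eQTL sets, MHC vs non-MHC), or let the adaptive mode find contiguous regions
with outlying effect-size variance.

## Model

For *n* individuals with phenotypes **y**, fixed effects **F b** and *M* SNP
classes,

    y = F b + g¹ + … + g^M + e,
    g^m ~ N(0, σ²_m K^m),    e ~ N(0, σ²_e I),
    K^m = X^m (X^m)′ / p_m,

where **X**^m holds the normalized genotypes of the *p_m* SNPs in class *m*
(centred by 2*f_j*, scaled by √(2*f_j*(1−*f_j*))). Equivalently each class is
a random-coefficient regression with its own per-SNP effect variance.

Variance components are estimated by average-information REML with
step-halving (the restricted log-likelihood never decreases), and a
component whose variance share stays below 0.01% for two consecutive
iterations is fixed at zero, so very many classes can be supplied safely.
When at most one class has full rank and the remaining classes together hold
fewer SNPs than individuals, the Woodbury identity plus a one-time
eigendecomposition gives the same estimates with no per-iteration n×n
matrix products.

Prediction models are portable: per-SNP effects are back-solved as
β^m = (σ̂²_m / p_m)(X^m)′ V̂⁻¹(y − F b̂), so new individuals are scored from
their genotypes alone, with training-sample allele frequencies frozen into
the model.

**Adaptive mode** tiles the genome with 75 kb windows (37.5 kb step), tests
each window's effect-size variance against the genomic background with a
likelihood-ratio test (a fast spectral test when individuals are unrelated,
an exact two-kinship REML test otherwise, statistic referred to χ²(1)),
merges windows with P < 10⁻⁶ together with overlapping neighbours below
P < 10⁻², and fits the resulting local regions plus a background region.

## Worked example

```python
import numpy as np
from multiblup import (
    SimScenario, assign_regions, simulate_genotypes, simulate_phenotype,
    normalize, fit_prediction_model, predict_phenotype, evaluate,
    heritability_shares,
)

# 900 unrelated individuals, 1500 SNPs; all heritability (h2 = 0.5)
# sits in the last of five genomic regions
g = simulate_genotypes(n=900, p=1500, seed=7)
regions = assign_regions(g.snps, n_regions=5)
sim = simulate_phenotype(normalize(g), regions,
                         SimScenario.preset(3, h2_total=0.5, seed=8))

rng = np.random.default_rng(9)
perm = rng.permutation(900)
test, train = perm[:150], perm[150:]
g_tr, g_te = g.subset(sample_idx=train), g.subset(sample_idx=test)

for method, kw in [("blup", {}), ("multiblup", {"regions": regions})]:
    pm, fit = fit_prediction_model(g_tr, sim.y[train], method=method, **kw)
    m = evaluate(predict_phenotype(pm, g_te), sim.y[test])
    shares = np.round(heritability_shares(fit), 3)
    print(f"{method:10s} test correlation {m.correlation:.3f}   "
          f"estimated variance shares {shares}")
```

prints

```
blup       test correlation 0.288   estimated variance shares [0.496]
multiblup  test correlation 0.545   estimated variance shares [0.    0.    0.003 0.035 0.495]
```

Both models recover a total heritability near the simulated 0.5, but BLUP
spreads it over all SNPs and reaches a test-set correlation of 0.29, while
the five-class model concentrates essentially the whole genetic variance in
the causal region (share 0.495) and nearly doubles the correlation. With a
trait whose heritability is spread evenly, the two methods perform alike.

## Command line

A thin CLI wraps the library: `multiblup qc | kinship | reml | adaptive |
score | cv | grs | stepwise | simulate`. Inputs are PLINK 1 binary filesets
(`.bed/.bim/.fam`) and whitespace-delimited FID/IID-keyed phenotype and
covariate tables; outputs are tab-separated tables whose headers record the
version, command line and seed. For example:

```
multiblup adaptive --bfile data --pheno pheno.txt --window-kb 75 \
    --step-kb 37.5 --p-seed 1e-6 --p-extend 1e-2 --mode auto --out run1
multiblup score --bfile newdata --model run1.effects.tsv --out scores.tsv
```

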