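# Methods

This note documents the models, the numerical choices, and what the
synthetic cohorts do and do not emulate.

## Mixture-model GWAS

### Model and sampler

Disease status y in {0,1} is treated as a linear trait (no liability-scale
transformation): y = mu + X b + Z beta + e. Dosages count copies of
allele2 and are column-centered but **not** variance-standardized, so
reported effects stay on the per-allele-copy scale of the 0/1 phenotype.
Each variant effect has the four-component prior
pi_1 delta_0 + sum_k pi_k N(0, gamma_k sigma2_g) with
gamma = (0, 1e-4, 1e-3, 1e-2).

One Gibbs iteration:

1. mu and the fixed-effect coefficients are sampled jointly from their
   conditional normals under flat priors (covariates are sampled, not
   pre-regressed out).
2. Every variant, in a freshly randomized order, has its class indicator
   sampled with probability proportional to pi_k times the marginal
   likelihood of its right-hand side under beta_j ~ N(0, gamma_k sigma2_g),
   then beta_j from the conditional normal (zero in class 1). The residual
   is adjusted incrementally (subtract/add the variant contribution), so an
   iteration costs O(nm).
3. pi ~ Dirichlet(alpha + class counts), alpha = (1,1,1,1).
4. sigma2_g and sigma2_e from scaled inverse-chi-square conditionals.

Post-burn-in draws are averaged within each chain; chains are averaged and
the reported statistic is the absolute value of that cross-chain signed
mean ("average first, then absolute", so two chains disagreeing in sign
cancel — disagreement is also surfaced as a per-variant between-chain
standard deviation).

### Variance priors — why the genetic prior scale is near zero

sigma2_e has a scaled inverse-chi-square prior with nu = 4 and scale
0.5 var(y): weakly informative, and immaterial because n dominates.

sigma2_g is different. The slab classes with gamma of 1e-4 and 1e-3 are,
for realistic Cjj = z_j'z_j, statistically indistinguishable from the
spike: their marginal-likelihood ratio against beta_j = 0 is ~1, so class
occupancy is prior-driven and every occupied slab draw contributes
E[beta_j^2]/gamma_k ≈ sigma2_g back into the sigma2_g update. The
conditional therefore has a prior-controlled fixed point near twice the
prior scale under the null; with a scale of 0.5 var(y) this keeps
sigma2_g ≈ 0.1–0.25 on data with no association at all, which in turn
leaves most per-variant posterior means above the 1e-4 reporting cutoff —
pure prior leakage masquerading as signal. The default genetic prior
scale is therefore 1e-4 var(y) (still proper, nu = 4). Under the null
sigma2_g then collapses toward zero and essentially no variant clears the
cutoff; with real signal the Sum beta^2/gamma term dominates the update
and the prior scale is irrelevant. Because a chain started at a tiny
sigma2_g can get stuck with an empty slab (the all-zero state is nearly
absorbing), chains are *initialized* at sigma2_g = sigma2_e = 0.5 var(y)
regardless of the prior scale; with 20k iterations and 5k burn-in the
between-chain standard deviation of sigma2_g is a few percent of its mean
on planted-signal cohorts.

### Numerical implementation

The kernel is numba-compiled. The genotype matrix and residual are held
in float32 — the matrix is streamed twice per iteration, so memory
bandwidth sets the runtime, and float32 rounding (~1e-7 relative) is far
below the Monte-Carlo error of the posterior means — while all model
parameters and accumulators are float64; the residual is rebuilt from
scratch in float64 every 500 iterations so rounding cannot drift.
Monomorphic (zero-variance) columns are given Cjj = 1e-12, which makes
their conditional posterior collapse to ~0 rather than divide by zero.

Default configuration: 20,000 iterations, 5,000 burn-in, 3 chains — sized
for cohorts of a few hundred samples and a few thousand variants, where
posterior summaries are stable across chains at that length.
`BayesRConfig.replication()` switches to 300,000/100,000/5 for full-size
cohorts. Per-chain seeds are spawned deterministically from the config
seed.

Degenerate inputs: non-finite phenotypes are rejected; a zero-variance
phenotype returns all-zero effects with a warning; gamma = (0,0,0,0)
forces beta = 0 and drives sigma2_e to the covariate-adjusted phenotypic
variance.

### Effect variants, loci, risk index, variance explained

* Effect variants: mean |effect| >= 1e-4 (inclusive bound — an effect of
  0.000104 qualifies), or alternatively the top N by that statistic with
  ties broken by genomic order. The 1e-4 cutoff is meaningful at
  genome-chip scale where each variant carries a sliver of signal; on
  small synthetic maps with planted moderate effects, per-variant
  posteriors are orders of magnitude larger and the top-N mode is the
  sensible reporting choice.
* Loci: single-linkage merge of effect variants on one chromosome with
  inter-variant gaps strictly below 1,000,000 bp (a gap of exactly 1 Mb
  splits). The member with the largest |effect| represents the locus; the
  risk allele is whichever allele is more frequent in cases at that
  variant.
* Risk index: per animal, the sum over loci of risk-allele weights at the
  locus top variant. Two weighting schemes ship — `half` (0/0.5/1 per
  locus) and `count` (0/1/2, exactly twice `half`) — because the two
  conventions circulate and they differ only by a factor of two; `count`
  is the default. A missing genotype contributes the locus mean weight.
* Variance explained: sequential (type-I) ANOVA from nested OLS fits,
  covariates entered first; per-term percentage = SS_term/SS_total x 100,
  so terms plus residual sum to exactly 100. A term that does not raise
  the design-matrix rank is reported with 0 df and flagged collinear.

## EHH, iHH and XP-EHH

EHH at a flanking marker is the probability that two haplotypes drawn
without replacement are identical at every site from the core to that
marker: sum_h n_h(n_h - 1)/(n(n - 1)) over distinct extended haplotypes.

* **Allele-specific mode** restricts to carriers of a chosen core allele
  (EHH = 1 at the core); this is the curve one plots around a focal risk
  allele.
* **Site-level mode** — the substrate of the two-population comparison —
  pools all haplotypes, includes the core site itself in the identity
  requirement, and normalizes by the core homozygosity so EHH(core) = 1.
  Published site-level EHH variants differ in exactly these choices; this
  definition is fixed here and documented, and the cross-population
  statistic depends only on its decay behaviour.

Extension proceeds marker by marker in each direction and stops at the
first marker where EHH < cutoff (default 0.05; that marker is kept on the
curve), at the chromosome border (flagged), or at an inter-marker gap
exceeding `max_gap_bp`. iHH is the trapezoidal integral over physical
distance with below-cutoff values set to zero first (no interpolation of
the crossing point — simpler and stated). Border-truncated curves are
integrated over their observed support by default; `discard_border=True`
drops them instead, matching tools that discard incomplete cores.

XP-EHH = log iHH_A - log iHH_B per variant (computed as a difference of
logs so swapping the panels negates scores bit-exactly), standardized by
the genome-wide mean and population standard deviation, with two-sided
normal p-values computed on the log scale (no underflow at large |z|).
Variants with zero iHH in either panel are dropped and reported; identical
panels raise an explicit zero-spread error rather than dividing by zero.

Region calling slides 1 Mb windows on a dense 0.1 Mb grid (the window
start grid uses the step, not the complementary 0.9 Mb stride — region
bounds then land on the 0.1 Mb grid); a window qualifies with >= 2
variants at -log10(p) >= 4, and qualifying windows that overlap or touch
merge. Per region: variant count, extreme count and percentage, and the
top variant by |standardized score|.

The per-variant scan kernel is numba-compiled, refining haplotype identity
groups incrementally (one array relabelling per marker step), so a
5,000-variant two-panel scan takes well under a second.

## Synthetic cohorts

The generator produces the statistical structure the two engines assume,
not a population-genetic simulation:

* **Haplotypes** follow a Li–Stephens-style copying model over a founder
  pool (default 20 founders): per-site template-switch probability 0.05
  and mutation probability 0.002, sites on a uniform 5 kb grid. This
  yields block-wise LD decaying over tens of kb — what the EHH machinery
  needs — but no coalescent-consistent allele-frequency spectrum,
  recombination hotspots, or cM map.
* **Substructure**: an optional second subpopulation copies from founders
  drawn at Balding–Nichols-drifted allele frequencies (drift parameter =
  Fst-like divergence). PC1 of the dosage matrix separates the two groups
  cleanly at divergence ~0.3+, which is what the PC-covariate tests rely
  on. Confounding is created by giving the subpopulation label a liability
  effect.
* **Phenotypes**: liability threshold model. Per-variant classes come from
  the same four-component mixture as the GWAS prior; realized genetic
  values are rescaled so the genetic fraction of liability variance equals
  the configured heritability exactly, and the case/control split is the
  empirical liability quantile, so case counts are exact at any n.
  `planted_causal_indices` forces chosen variants into the largest class
  with fixed-magnitude, random-sign effects for recovery experiments.
* **Sweeps**: within the target phenotype group, haplotypes are replaced
  by copies of one donor haplotype over core ± flank until the donor
  frequency reaches the target. Copying a fixed span produces a *flat*
  XP-EHH plateau across it (every in-span variant has near-equal iHH), so
  the flank radius — default 100 kb — is the localization scale of the
  resulting signal; a forward simulation would instead give a core-peaked
  decay. The default is chosen so the expected localization matches the
  100 kb scale at which sweep candidates are evaluated.

Consequently, passing tests on these cohorts demonstrate correctness of
the estimators under idealized LD and exchangeability — they do not
demonstrate robustness to genotyping error, uncertain phasing (panels are
generated phased; phasing is out of scope), relatedness, or imputation
artefacts present in real SNP-chip cohorts.

Problem sizes used by the validation suite and the acceptance script were
chosen as the smallest at which the statistical contrasts are
unambiguous: GWAS recovery at n = 600, m = 3,000 with 5 planted effects;
GWAS null at n = 400, m = 2,000; XP-EHH null calibration on exchangeable
150–200-sample panels of 5,000 variants; sweep detection at n = 300,
m = 3,000 (15 Mb), 80% case-carrier frequency.

## Standard statistics

The small-sample tests wrap the standard library implementations —
Pearson chi-square with and without Yates' continuity correction
(scipy.stats.chi2_contingency; the correction truncates at zero), Welch's
t with Satterthwaite df (scipy.stats.ttest_ind), logistic regression by
IRLS (statsmodels Logit; non-convergence and separation are flagged and
yield missing p-values) — and the test suite checks them against closed
forms and against R's stats package on frozen fixtures. The allelic
chi-square scan uses allele-count 2x2 tables with missing genotypes
excluded per variant, matching the convention of standard GWAS tooling.
LD r^2 is the squared Pearson correlation of dosages (genotype mode) or
of phased alleles (haplotype mode). PCA covariates come from the SVD of
the standardized dosage matrix with a deterministic sign convention.

## Known limitations

* The linear model on 0/1 status ignores the binary likelihood; this
  mirrors the analysed approach but means effect sizes are on the
  observed, not liability, scale.
* XP-EHH standardization is genome-wide with no allele-frequency binning;
  on maps where a sweep occupies a large fraction of all variants the
  null mean/sd are contaminated and power drops.
* The 1e-4 effect-variant cutoff is only meaningful at genome scale; use
  top-N reporting on small maps.
* QC order is fixed (variant missingness, then sample missingness, then
  MAF recomputed); LD pruning is a simple greedy r^2-window filter, not a
  reimplementation of any specific tool's pruner.
* Coordinates are 1-based inclusive; chromosome X conventions and
  imputation are out of scope.
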