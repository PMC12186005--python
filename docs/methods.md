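# Methods

## The synthetic study design

The generator emulates a multi-location fjord seascape survey: ten sampling
locations with unequal sample sizes (defaults 17, 23, 24, 12, 15, 22, 20,
22, 20, 27 — 202 individuals, 12–27 per site), six environmental variables
(temperature °C, salinity g/kg, oxygen mL/L, nitrate µM, phosphate µM,
silicate µM) summarised per location as mean/min/max/range, and RAD-tag
SNP loci grouped 1–3 per tag.

* **Neutral loci.** Per-deme alternate-allele frequencies follow the
  Balding–Nichols model: `p_d ~ Beta(p(1-F)/F, (1-p)(1-F)/F)` with
  ancestral frequency `p ~ U(0.1, 0.9)` and drift parameter `F = 0.05` by
  default. `F` equals the expected Weir–Cockerham FST among demes, which is
  what makes the simulator a quantitative oracle for the estimator.
* **Adaptive loci.** Deme frequency is a logistic cline on the z-scored
  environmental value: `expit(alpha + beta * z(env))`, with
  `alpha ~ U(-0.5, 0.5)`, `|beta| = 1.5` by default and a random sign, and
  loci assigned round-robin to temperature, salinity and oxygen. Working on
  z-scores makes `beta` comparable across variables. A `cline_model =
  "linear"` option plants frequencies linear in the gradient
  (`0.5 + 0.15 beta z`, clipped to [0.02, 0.98]) — the textbook
  directional-selection cline used in the APS model-selection replicates,
  where the planted APS–environment relationship must itself be linear for
  "selects the linear model" to be a well-posed success event.
* **Environment.** Each variable has a fixed ten-deme profile (with
  half-spread giving min/max); profiles are correlated the way fjord water
  masses are (temperature and oxygen broadly latitudinal, salinity and
  silicate estuarine-patchy) but none are collinear. The values are
  plausible magnitudes for a temperate fjord system, not claims about any
  particular site.
* **Genotypes and depths.** Genotypes are `Binomial(2, p_deme)`; total read
  depth per called genotype is negative-binomial (mean 30, shape 5), split
  `Binomial(depth, 1/2)` between alleles in heterozygotes. Missingness is
  entrywise Bernoulli with combined rate `1-(1-r_locus)(1-r_sample)`
  (defaults 0.03 and 0.02).
* **Paralogs.** Each paralog merges two independent diploid copies: the
  apparent call is heterozygous whenever the four underlying allele copies
  disagree, and alt reads are `Binomial(depth, copies/4)` at twice the
  singleton depth. This is the simplest mechanism that produces the joint
  H/D signature HDplot targets; higher-order duplicate families are not
  modelled.

What the generator does **not** emulate: linkage disequilibrium beyond
shared tags, coalescent history and migration, temporal selection dynamics,
genotyping-error modes other than paralog collapse, and spatial
autocorrelation of individuals within a location. Passing tests therefore
demonstrate correctness and calibration of the statistics under the stated
sampling model, not robustness to every pathology of real RAD-seq data.

## Filtering cascade

Order: per-location MAF ≥ 0.05 → call rate ≥ 50 % per locus, then per
sample → ≥ 90 % per locus, then per sample → per-location MAF ≥ 0.1 →
HDplot (retain H < 0.6 and |D| < 5) → HWE exact-test filter → one SNP per
tag. Loci are always filtered before samples within a call-rate tier.

* The per-location MAF rule retains a locus if the threshold is met in at
  least one location (configurable to "all"): locally common variants are
  the object of a seascape scan, so a locality-aware retain rule is the
  conservative default.
* The HWE filter removes a locus when the exact test rejects (p < 0.05) in
  three or more locations (configurable); the exact test uses the standard
  two-sided sum-of-less-probable-outcomes convention, not mid-p, and is
  computed in log-gamma space with renormalisation.
* One-SNP-per-tag keeps the SNP with the highest overall multi-population
  θ̂ computed on the pre-selection matrix; exact ties break to the smaller
  position. Note this selection rule biases the retained loci's FST upward
  relative to the simulated drift parameter — visible in the worked example
  (neutral global FST ≈ 0.067 at F = 0.05).

## Differentiation and diversity

Weir–Cockerham variance components a/b/c are computed per locus with
missing genotypes excluded pairwise; populations without data at a locus
drop out of that locus's component sums. Multi-locus θ̂ is the ratio of
sums Σa/Σ(a+b+c), never a mean of ratios; negative estimates are reported
as computed. Pairwise significance permutes individuals between the two
locations with the +1-corrected one-sided p-value; the global CI bootstraps
loci (the CI convention for a multi-locus ratio estimator). Unbiased
H<sub>E</sub> = 2n/(2n−1)·2p(1−p); F<sub>IS</sub> = 1 − H<sub>O</sub>/H<sub>E</sub>, undefined for monomorphic
cells. The Mantel test correlates θ̂/(1−θ̂) with Euclidean distance on the
supplied coordinates, permuting rows/columns of the geographic matrix; an
exhaustive mode enumerates all n! permutations for n ≤ 7.

## Outlier scans

* **FST–heterozygosity envelope** (`fsthet_scan`): loci are binned into 25
  quantile bins of overall expected heterozygosity; the 2.5 %/97.5 %
  empirical quantiles of θ̂ within a 3-bin sliding window form the
  envelope. Pooling the window's loci before taking the quantile (rather
  than averaging three per-bin quantiles) keeps the null flag rate pinned
  at the nominal 5 %; averaging noisy quantiles measurably inflated it.
  Bins under 20 loci merge leftward. An intrinsic property of any
  quantile-envelope scan is that it cannot flag more of a bin than the
  nominal tail, so its recall calibration uses planted fractions below that
  tail (1 % contamination in the recovery tests).
* **PCA/Mahalanobis** (`pca_outlier_scan`): standardized, mean-imputed
  genotypes are regressed on the top-K genotype PCs; the K coefficient
  z-scores per locus give a Mahalanobis distance whose null is χ²(K) after
  dividing by the median-based genomic inflation factor; BH q < 0.05 flags
  divergent loci.
* **Latent-factor GEA** (`gea_lfmm_lite`): per locus, OLS of imputed dosage
  on the individual-level environmental value plus K latent factors; the
  environment coefficient's χ², inflation-corrected, gives the p-value.
  The latent factors are the top-K PCs of the genotypes **after regressing
  out the environment**. Factors computed from the raw genotype matrix
  absorb the tested gradient itself (the environment is constant within
  demes and thus lies inside the structure subspace), driving power to
  zero; residualising first is the one-step analogue of the joint
  factor-and-effect estimation that latent-factor mixed models perform.
  Measured on the synthetic design: raw-PC factors recover 0/20 planted
  clines, residualised factors 20/20 at the same 5 % FDR with a 4.6 %
  empirical type-I rate.
* **RDA** (`rda_scan`): mean-imputed centered genotypes are regressed on
  the z-scored, collinearity-pruned environment matrix (pairwise |r| > 0.99
  drops a variable with a warning); the SVD of the fitted values gives at
  most as many constrained axes as environment variables. Axis significance
  permutes which **location** receives which environment row — the
  location is the exchangeable unit for deme-level predictors, and free
  individual-level permutation lets residual drift structure masquerade as
  constrained variance. Axes are interpreted sequentially (once an axis
  fails at α = 0.05, smaller axes are not used). On significant axes, loci
  beyond 3 SD of the loading mean are flagged and annotated with the most
  correlated variable.
* **Consensus**: a locus flagged divergent by ≥ 2 methods (counted across
  the PGD/GEA union by default; a within-class mode exists) is a putative
  adaptive locus; the shared set is the PGD∩GEA intersection of qualifying
  loci; balancing-flagged loci are excluded from both the adaptive and the
  neutral set. A locus may associate with several environmental variables;
  per-variable sets are kept separately.

## Additive polygenic scores

Orientation comes from the OLS slope of genotype on the environmental value
each individual inherits from its location (slope exactly 0 orients
positive by convention; monomorphic loci are excluded with a warning).
Scores sum over, by default, the shared consensus loci the GEA scans
associated with each variable (falling back to all shared loci; an
`all_shared` mode forces the full set). A missing genotype contributes its
orientation-consistent expectation `2f̂` (or `2−2f̂`) from the location
allele frequency, so APS bounds [0, 2L] and the reflection symmetry
`APS → 2L − APS` under global allele relabelling hold exactly.

Model comparison uses plain Gaussian AIC (not AICc), k counting intercept,
slopes, and the residual variance: AIC = 2k − 2 lnL̂ with
lnL̂ = −n/2·(ln(2π·RSS/n)+1). R² and the F-test p-value are
relative to the intercept-only null. One consequence worth stating: when
the true relationship is exactly linear, AIC still prefers the quadratic
whenever its likelihood-ratio statistic exceeds 2, which happens ~16 % of
the time by chance. The replicate success criterion for directional
selection therefore asks that the linear model beats the null with the
orientation-consistent (positive) slope sign; the strict "linear is the
single AIC winner" rate is reported alongside and sits near the ~84 %
theoretical ceiling. The worked example shows the same effect: strongly
sigmoidal planted clines can make the quadratic model genuinely better.

## Numerical and reproducibility choices

* Missing genotypes use a dedicated sentinel code; no −1 arithmetic.
  Monomorphic loci yield p = 1 exact tests, NaN F<sub>IS</sub>, and NaN θ̂
  components, and are excluded from ratio-of-sums pooling.
* Permutation p-values use the +1 correction and a caller-supplied seed;
  the pipeline derives per-stage child seeds from one master seed via
  `SeedSequence.spawn`, so stages are independently reproducible and a run
  directory's manifest (config hash + SHA-256 of every artifact) is
  byte-identical across reruns.
* VCF output has a fixed header (no dates) for byte-stable round trips.
* Problem sizes in the tests and acceptance script — 2,000-locus
  calibration datasets, 100–500 replicate suites at 200 loci, 199–999
  permutations — were chosen as the smallest designs at which the binomial
  tolerances of the calibration checks are meaningful.

## Known limitations

* The two PGD and two GEA scans are representatives of their method
  classes, not re-implementations of any specific published tool; Bayesian
  scan families are out of scope.
* Imputation by locus means for the ordinations slightly shrinks loadings
  at high missingness; the filter cascade runs first, which caps
  missingness at 10 %.
* The RDA variable attribution (max |correlation|) is only as identifiable
  as the environment profiles are decorrelated; strongly collinear
  gradients share credit.
* Structure/admixture inference, LD pruning beyond one-SNP-per-tag,
  genotype likelihoods, and functional annotation are out of scope.
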