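# seascapegen

A seascape-genomics analysis pipeline for detecting genomic signals of local
adaptation in marine populations sampled along environmental gradients.
Given biallelic SNP genotypes (VCF), a sample→location popmap, and a
per-location table of environmental summaries, it runs:

1. **QC filtering** — an iterative cascade of per-location minor-allele-
   frequency filters, tiered call-rate filters, HDplot paralog removal,
   Hardy–Weinberg exact-test filtering, and one-SNP-per-RAD-tag selection.
2. **Outlier scans** — two population-genetic-differentiation (PGD) scans
   (empirical F<sub>ST</sub>–heterozygosity quantile envelope; PCA/Mahalanobis with
   genomic-inflation correction) and two genotype–environment-association
   (GEA) scans (latent-factor-corrected regression; redundancy-analysis
   loadings), combined by a ≥2-method consensus rule into putative adaptive,
   neutral, and balancing sets.
3. **Population-genetic statistics** — H<sub>O</sub>, unbiased H<sub>E</sub>, F<sub>IS</sub>; pairwise and
   global Weir–Cockerham F<sub>ST</sub> with permutation tests and bootstrap CIs; a
   Mantel test of isolation by distance on linearized F<sub>ST</sub>.
4. **Additive polygenic scores (APS)** — per-individual sums of
   favored-allele counts across adaptive loci, with null/linear/quadratic
   model comparison by AIC along each environmental gradient.

A fully seeded synthetic-data generator (Balding–Nichols neutral loci,
logistic adaptive clines, merged-duplicate paralogs, negative-binomial read
depths) provides a truth table for every locus, so each stage's sensitivity
and calibration can be measured without any external data.

## The statistics at the core

* **Weir–Cockerham θ̂** is estimated from the among-population (a),
  among-individual (b), and within-individual (c) variance components;
  multi-locus values pool as Σa / Σ(a+b+c).
* **HDplot** flags paralogs with the per-locus heterozygote proportion
  H and read-ratio deviation D = (x − n/2)/√(n/4), where n is the total
  read count in heterozygotes and x the reference-allele reads; singleton
  loci satisfy H < 0.6 and |D| < 5.
* **HWE exact test**: P(n<sub>Aa</sub> | n<sub>A</sub>, n) = n!/(n<sub>AA</sub>! n<sub>Aa</sub>! n<sub>aa</sub>!) · 2^n<sub>Aa</sub> / C(2n, n<sub>A</sub>);
  the two-sided p-value sums all configurations no more probable than the
  observed one.
* **APS**: with genotypes coded 0/1/2 (alternate-allele count), each locus
  is oriented by the sign of the OLS slope of genotype on the environmental
  variable (positive slope → score = genotype, negative → 2 − genotype),
  and APS is the per-individual sum, compared across OLS models by Gaussian
  AIC = 2k − 2 ln L̂.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
design (10 locations, 202 individuals, 2,000 neutral + 100 adaptive + 50
paralog loci):

```bash
python analysis/01_simulate.py
python analysis/02_filter.py
python analysis/03_scan.py
python analysis/04_popgen.py
python analysis/05_aps.py
```

`02_filter.py` prints the filter cascade and paralog scoring:

```
                                  step  samples  loci
                                 input      202  2150
                           MAF >= 0.05      202  2150
            call rate per locus >= 50%      202  2150
           call rate per sample >= 50%      202  2150
            call rate per locus >= 90%      202  2148
           call rate per sample >= 90%      202  2148
                            MAF >= 0.1      202  2148
HDplot singletons (H < 0.6, |D| < 5.0)      202  2097
  HWE exact p >= 0.05 in > 2 locations      202  2096
         one SNP per tag (highest FST)      202  1073

HDplot: 100% of planted paralogs removed, 0.0% of singletons lost
```

`03_scan.py` and `04_popgen.py` report the consensus sets and the contrast
between adaptive and neutral differentiation:

```
consensus: PGD=58  GEA=58  shared=58
recovery vs truth: recall=100%  false-discovery=3.4%
adaptive (  58 loci): ... global FST=0.3694 CI[0.3528, 0.3852]  Mantel r=0.894 (p=0.001)
neutral  ( 983 loci): ... global FST=0.0671 CI[0.0649, 0.0691]  Mantel r=-0.124 (p=0.801)
```

The adaptive loci are far more differentiated than the neutral background
and show a strong isolation-by-distance signal, exactly as planted.
`05_aps.py` then shows the polygenic scores tracking the gradients
(e.g. `temperature_max  best=linear  linear R2=0.961`).

The same pipeline runs from a single config via the CLI:

```bash
seascapegen run --seed 1 --outdir results/run
```

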