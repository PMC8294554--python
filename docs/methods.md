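# Methods

## Retrospective simulation model

Each simulated dataset mimics a case-control GWAS panel: n₁ cases and n₀
controls genotyped at m biallelic SNPs, of which m₁ are causal. Sampling is
retrospective — genotype conditional on disease status with fixed group
sizes — which is exactly what a case-control ascertainment produces and
avoids the waste of prospective sampling at low prevalence.

For a causal SNP with minor-allele frequency p, population genotype
frequencies are Hardy–Weinberg, f = (q², 2pq, p²) over (AA, Aa, aa), q = 1−p.
Genotypes are indexed throughout by the minor-allele count g ∈ {0, 1, 2}.

* **Penetrance model.** Given penetrances π(g) = P(disease | g), Bayes' rule
  gives exactly

      P(g | case) = f(g)·π(g) / Σ f·π,     P(g | control) = f(g)·(1−π(g)) / Σ f·(1−π).

  Only penetrance *ratios* affect these distributions, so rescaling all π to
  a target prevalence changes nothing retrospectively.

* **Odds-ratio model.** Controls are drawn at the population frequencies f
  (the rare-disease approximation: with prevalence ≪ 1, controls are
  essentially the population) and cases with probability ∝ f(g)·w(g). The
  default homozygote rule is **recessive**, w = (1, 1, OR): the odds ratio
  attaches to the minor-allele homozygote and heterozygotes carry no risk.
  A multiplicative rule, w = (1, OR, OR²), is available via
  `hom_rule="mult"`. The recessive default is deliberate: under a
  multiplicative generative model the additive test is asymptotically the
  locally most powerful of the three codings, so comparisons between codings
  are only informative when the generative architecture departs from
  additivity; the recessive rule is the configuration under which this
  package's scenario-1 experiment is defined, and it is the setting our
  full-grid calibration runs reproduce the expected AUC ordering
  (recessive > additive > dominant) under.

Null SNPs are phenotype-independent; each draws a population MAF uniformly
from [0.05, 0.5] (mirroring simulators that specify a frequency range) and
all individuals sample from HWE at that MAF. Causal SNPs occupy the first
m₁ columns; downstream analysis never uses position, only the sidecar truth
labels.

Default experiment conditions (one dataset per grid cell and replicate):
n₁ = n₀ = 1,000; m = 10,000; m₁ = 100; scenario 1 crosses OR ∈ {1.1, …, 2.0}
with causal MAF ∈ {0.05, …, 0.50}; scenario 2 fixes π_AA = 0.01, π_aa = 0.1
and crosses π_Aa ∈ {0.01, …, 0.10} with the same MAF grid.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent), population structure and relatedness, covariates, genotyping
error and informative missingness (missingness is injected uniformly at
random only for QC testing), sex chromosomes. Passing tests therefore speak
to the statistical behaviour of the codings under idealized independent
SNPs, not to confounding-driven artifacts in real panels.

## Quality control

Filters run in a fixed order: (1) drop individuals with > 5% missing
genotypes; (2) drop SNPs with > 5% missingness among remaining individuals;
(3) drop SNPs with pooled-sample MAF < 0.05 (computed over non-missing
genotypes); (4) drop SNPs whose HWE test in **controls** has p < 0.01.
Individual removal precedes per-SNP statistics because it changes all of
them. HWE is tested in controls only: true risk loci deviate from HWE among
cases, and filtering on a pooled or case stratum would preferentially delete
exactly the non-additive signals this package studies. The HWE test is the
1-df Pearson goodness-of-fit against expectations at the sample allele
frequency; monomorphic SNPs return p = 1. Simulated experiments skip QC by
default (the generator produces clean HWE data); it can be enabled to
exercise the full pipeline.

## Association scoring

Genotypes are re-polarized per SNP so that "a" is the **sample** minor
allele (pooled cases + controls); ties at frequency 0.5 keep the stored
orientation. This is what a real analysis would do — population frequencies
are unobservable — and it matters: near MAF 0.5 a strong risk allele can
exceed frequency 0.5 in the ascertained sample, flipping which homozygote
the recessive coding tests.

* **Chi-square.** A 2×2 phenotype-by-exposure table per SNP: for the
  additive coding the allele table (each individual contributes two
  alleles); for dominant/recessive, carrier tables (≥1 copy / 2 copies).
  1-df Pearson statistic, no continuity correction; tables with a zero
  margin score 0 with p = 1. This is the unique construction that uses each
  coding and stays 1-df throughout.
* **Logistic.** Case status on intercept + coded genotype, fit by
  Newton/IRLS. Because the coded genotype takes ≤ 3 values the likelihood
  depends only on the 2×3 phenotype-by-genotype counts, so all SNPs of a
  dataset are fit simultaneously on aggregated counts (this is what keeps a
  600,000-fit experiment in seconds). Convergence: max |Δβ| < 1e-8 within
  25 iterations; p is the two-sided Wald p of the genotype coefficient.
  Degenerate SNPs (constant coding, single phenotype class) and separated
  or non-converged fits return NA.

Per dataset and (coding, method) column, p-values are BH step-up adjusted
over the m tested SNPs (NA excluded from m) and scored as −log₁₀(p) with p
floored at 1e-300 to keep scores finite. NA results are excluded from score
means and never counted significant.

Calibration note: on 100k null SNPs (MAF uniform in [0.05, 0.5], 1,000+1,000
samples) the measured type-I error at α = 0.05 is ≈ 0.049 for the chi-square
tests and the additive/dominant logistic Wald tests, ≈ 0.045 for the
recessive logistic Wald test — the Wald statistic is slightly conservative
when the homozygote-carrier count is small, a known finite-sample property
worth remembering when interpreting recessive logistic results at low MAF.

## Evaluation statistics

* **Discrimination** d = (mean score of causal SNPs)/(mean score of null
  SNPs); NA if a class is empty or the null mean is zero. d is
  scale-invariant in the scores.
* **Precision** at BH-adjusted p ≤ 0.05: TP/(TP+FP); NA when nothing is
  called. Raw (unadjusted) scores feed d; BH enters only precision.
* **dOR / PR**: for two codings, the per-dataset ratio d₁/d₂ (or
  precision₁/precision₂) averaged over datasets — a mean of ratios. Pairs
  with NA in either member are dropped. The ratio of dataset means is also
  reported for transparency; the two differ under heterogeneous grids.
* **ROC/AUC**: per dataset, TPR and FPR of "score ≥ t" over a shared
  threshold grid of 1,001 evenly spaced values from 0 to 301 (just above the
  score cap, so the curve is anchored at (1,1) and (0,0)); TPR/FPR are
  averaged pointwise across datasets and the AUC is the trapezoid area of
  the mean curve sorted by FPR. Pointwise averaging requires the shared
  grid; per-dataset AUCs (used for the t tests) use the same grid and rule.
* **t test**: paired two-tailed t test on per-dataset AUC differences —
  paired because the same datasets are scored under both codings; NA on
  zero-variance differences.

## Reproducibility and numerics

One experiment seed drives everything: dataset k draws its own 31-bit seed
from the SeedSequence substream (seed, k), so any dataset can be regenerated
independently and runs are bit-reproducible. The experiment driver writes
per-dataset evaluations, AUC and dOR/PR summary tables, mean-ROC points and
a JSON manifest (config, seed, version, failures).

Numerical edge cases and tie-breaks: sigmoid arguments are clipped at ±30
and singular information matrices marked NA (separation); the score cap of
300 (p floor 1e-300) bounds −log₁₀(p) where the chi-square tail underflows;
monomorphic SNPs are p = 1 in the HWE test and NA in logistic fits; PED
files written by the package carry a `counted_allele` column in the truth
sidecar so reading is an exact inverse even for SNPs whose stored allele is
the sample-major one (bare PED/MAP files fall back to sample-frequency
inference, ties toward the lexicographically later allele).

Experiments in the test suite and the acceptance script run each scenario
grid at one replicate per cell (100 datasets per scenario); the package's
default experiment size. With count-aggregated scoring this is a few
minutes of CPU; the `replicates` field scales it up without further changes.

## Known limitations

* The odds-ratio branch models only the two homozygote rules above; general
  (OR_het, OR_hom) pairs and prevalence-corrected control frequencies are
  not implemented.
* Scenario 2 with elevated heterozygote penetrance (π_Aa ≫ π_AA) produces
  very strong additive signals at this sample size; most grid cells saturate
  the score cap, and comparisons between codings there reflect the cap and
  the sample-minor flip as much as the tests themselves.
* The dominant coding's precision is frequently NA in weak grid cells (no
  BH discoveries), so PR aggregates for the dominant model summarize only
  the stronger cells.
* QC thresholds are fixed scalars; no relatedness, heterozygosity or batch
  filters.
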