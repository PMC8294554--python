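# gwasmodels

Case-control genome-wide association studies (GWAS) almost always score SNPs
under an **additive** genetic model: the genotypes AA, Aa, aa (with "a" the
minor allele) are coded 0, 1, 2. Because a case-control phenotype is binary,
a **recessive** (0, 0, 1) or **dominant** (0, 1, 1) coding can be a better
match for the architecture of the trait. `gwasmodels` is a simulation
pipeline for quantifying that choice: it generates case-control genotype
datasets with known causal SNPs, scores every SNP under the three codings
with both a chi-square test and univariate logistic regression, and measures
how well each coding separates causal from null SNPs.

It is aimed at statistical geneticists and methods students who want a
controlled, reproducible testbed for genetic-model choice.

## What it computes

**Simulation.** Datasets of 1,000 cases + 1,000 controls and 10,000 biallelic
SNPs (100 causal) are drawn retrospectively: genotypes conditional on disease
status. Controls follow Hardy–Weinberg (HWE) proportions
(q², 2pq, p²) at the SNP's minor-allele frequency (MAF) p; case genotype g is
drawn with probability ∝ f(g)·w(g). Two disease models set the weights w:

* *odds-ratio model* (scenario 1): w = (1, 1, OR) — the odds ratio applies to
  the minor-allele homozygote (a recessive risk model; a multiplicative rule
  w = (1, OR, OR²) is available as an option). Grid: OR ∈ {1.1, …, 2.0} ×
  MAF ∈ {0.05, …, 0.50}.
* *penetrance model* (scenario 2): w(g) = π(g), the probability of disease
  given genotype, with π_AA = 0.01, π_aa = 0.1 and π_Aa ∈ {0.01, …, 0.10};
  controls use weights 1 − π(g). Same MAF grid.

**Association.** Per SNP and coding: a 1-df Pearson chi-square test (allele
table for the additive coding, carrier tables for dominant/recessive) and a
logistic regression Wald test on the coded genotype, both as in standard
GWAS practice. p-values are Benjamini–Hochberg (BH) adjusted per dataset and
transformed to scores −log₁₀(p).

**Evaluation.** For each dataset and coding:

* discrimination d = mean score of causal SNPs / mean score of null SNPs;
* precision of calling SNPs with BH-adjusted p ≤ 0.05 positive;
* ROC of causal-vs-null classification over a shared score-threshold grid,
  TPR/FPR averaged pointwise across datasets, trapezoid AUC.

Codings are compared by dOR = d₁/d₂ and PR = Precision₁/Precision₂ (averaged
per-dataset ratios) and by paired t tests on per-dataset AUCs.

A standard QC module (per-individual/per-SNP missingness ≤ 0.05, MAF ≥ 0.05,
HWE in controls at p ≥ 0.01) is included for pre-processing experiments.

## Worked example

```python
import gwasmodels as gm

spec = gm.SimulationSpec(n_cases=1000, n_controls=1000, n_snps=10000,
                         n_causal=100, causal_maf=0.3, odds_ratio=1.8, seed=42)
data = gm.simulate_dataset(spec)
scored = gm.score_dataset(data)
for model in ("AM", "DM", "RM"):
    sub = scored[(scored.model == model) & (scored.method == "chi_square")]
    d = gm.discrimination(sub["score"], sub["is_causal"])
    prec, n = gm.precision_at_cutoff(sub["p_bh"], sub["is_causal"])
    tpr, fpr = gm.roc_curve(sub["score"], sub["is_causal"])
    auc = gm.auc_from_points(tpr, fpr)
    print(f"{model}: d={d:5.2f}  precision={prec:.3f} ({n:3d} calls)  AUC={auc:.3f}")
```

prints

```
AM: d= 7.39  precision=1.000 ( 28 calls)  AUC=0.976
DM: d= 2.67  precision=nan (  0 calls)  AUC=0.802
RM: d=10.77  precision=0.936 ( 78 calls)  AUC=0.996
```

Under this recessive disease model (homozygote OR 1.8, MAF 0.3) the
recessive coding separates causal from null SNPs best: its average causal
SNP scores ~10.8× the null average (vs 7.4× for additive), it calls 78 SNPs
significant at BH 0.05 with 93.6% precision, and its causal-vs-null AUC is
0.996. The dominant coding dilutes the homozygote signal with unaffected
heterozygote carriers and detects nothing at this cutoff.

The same pipeline is scriptable from the shell:

```sh
gwasmodels simulate --scenario 2 --maf 0.3 --pi-het 0.05 --seed 1 --out data/sim
gwasmodels assoc --in data/sim --out data/assoc.tsv
gwasmodels evaluate --assoc data/assoc.tsv --out data/eval.tsv
gwasmodels run-experiment --scenario 1 --seed 1 --out runs/scenario1
```

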