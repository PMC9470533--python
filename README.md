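# rge — gene–environment correlation across families and regions

Polygenic scores do not only index direct genetic effects: when people (or
their parents) sort into environments that correlate with their genotypes,
the scores absorb those environments too. `rge` is a toolkit for quantifying
that gene–environment correlation (rGE) in two complementary designs, with a
synthetic-cohort generator that has known ground truth for every mechanism:

- **Sibling decomposition.** Five random-intercept mixed models split the
  association between a polygenic score (PRS) and a phenotype Y into
  within-family, between-family and between-region components. With family
  mean m_j, region mean m_k and within-family deviation w = PRS − m_j:

  1. Y = α₀ + β·PRS + γ_j + ε
  2. Y = α₀ + β_W(PRS − m_j) + β_B·m_j + γ_j + ε
  3. Y = α₀ + β_W(PRS − m_k) + β_B·m_k + γ_j + γ_k + ε
  4. Y = α₀ + β_W(PRS − m_j − m_k) + β_BF(m_j − m_k) + β_BR·m_k + γ_j + γ_k + ε
  5. Y = α₀ + β_W(w − w̄_k) + β_B·w̄_k + γ_j + γ_k + ε

  A drop in β_W from model 2 to model 4 means part of the "within-family"
  signal is really regional; the significance of that drop comes from a
  bootstrap over sibling pairs that re-estimates both models per replicate
  (the difference over its bootstrap SD, squared, is χ²(1) under the null).
  Model 5's between-region coefficient on w̄_k detects *active* rGE:
  migration by one's own genetic deviation from the family.

- **Region-controlled GWAS and LD score regression.** Association scans with
  sex, age, genotype PCs and dummy fixed effects for geographic regions
  (birthplace, current address, or both), with covariates absorbed once by
  projection (Frisch–Waugh–Lovell). SNP heritability is the slope of the
  weighted regression of χ² on the LD score (h² = slope·M/N); genetic
  correlation comes from regressing z₁z₂ on the LD score. Because corrected
  and uncorrected scans share the sample, changes in h² or r_g are tested by
  differencing delete-one-block jackknife estimates computed on the same
  genome blocks — a dependence-aware Z test — with BH-FDR across traits.

The simulator builds sibling pedigrees with block-LD genotypes, regions on a
grid with a spatially smooth SES field, passive rGE (parents sort into birth
regions by midparent genetic value), active rGE (adults migrate by their own
within-family deviation), and phenotypes with configurable direct
heritability, nurture, region and family environmental variance. See
`docs/methods.md` for the full model and its limitations.

## Worked example

```python
import numpy as np
from rge import SimConfig, simulate_sibling_cohort, decompose_trait, bootstrap_within_diff

cfg = SimConfig(n_families=5000, n_regions=100, n_snps=1000, seed=7)
cohort, layout, truth = simulate_sibling_cohort(cfg)

fits, table = decompose_trait(cohort, "pheno_ses", model_ids=(2, 4))
print(table[table.term.str.startswith("PRS")]
      [["model", "term", "estimate", "se", "t", "p"]].round(3).to_string(index=False))

res = bootstrap_within_diff(cohort, "pheno_ses", n_boot=500, seed=7)
print(f"within-effect change (model 2 vs 4): "
      f"diff={res.difference:.3f}  SE={res.se:.3f}  chi2={res.chi2:.1f}  p={res.pvalue:.2e}")
```

prints

```
 model   term  estimate    se      t   p
     2  PRS_w     0.672 0.012 56.534 0.0
     2 PRS_bf     0.613 0.012 53.168 0.0
     4  PRS_w     0.249 0.005 50.868 0.0
     4 PRS_bf     0.400 0.008 47.372 0.0
     4 PRS_br     2.116 0.035 60.900 0.0

within-effect change (model 2 vs 4): diff=0.423  SE=0.011  chi2=1368.1  p=1.81e-299
```

This cohort was generated with both rGE channels on (w_passive = w_active =
0.5, region SES explaining 20% of the phenotype). Read it as follows: in
model 2 the within-family effect (0.672) looks like a clean genetic effect,
but adding the between-region terms (model 4) cuts it to 0.249 — the
bootstrap puts the drop at 38 SDs — because much of the "individual-level"
signal was regional sorting. The large between-region coefficient (2.116 per
unit of region-mean PRS, which has small variance) carries the environmental
SES gradient that the score tags through migration and parental sorting. On
a no-rGE cohort the same contrast is null (type-I error ≈ 5%, tested).

The same library drives a shell interface for users with their own tables:

```bash
rge simulate --config run.yaml --out-dir data/
rge decompose --pheno data/cohort.tsv --trait pheno_ses --models 1,2,3,4,5 --out decomp.tsv
rge boot-test --pheno data/cohort.tsv --traits pheno_ses --n-boot 1000 --seed 1 --out boot.tsv
rge gwas --geno data/genotypes --pheno data/cohort.tsv --trait pheno_ses \
    --regions current --n-pcs 10 --min-region-n 100 --out ses.sumstats
rge ldsc --sumstats ses.sumstats --ref-geno data/genotypes --out h2.json
rge run-all --config run.yaml --out-dir full_run/
```

Inputs are plain text: tab-delimited phenotype/covariate tables (FID, IID,
region_birth, region_current, sex, age, PRS, pheno_*), genotypes as a 0/1/2
matrix with a SNP map or as VCF, whitespace-delimited summary statistics
(SNP, A1, A2, FRQ, BETA, SE, Z, N).

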