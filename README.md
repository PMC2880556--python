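# natfert

Pedigree-based genetics of natural male fertility, built around the CFTR
(TG)m–polyT–Met470Val system: phenotype construction, relatedness-corrected
association in founder-population pedigrees, nonparametric survival
comparison of time to the kth birth, rule-based three-locus haplotype
phasing, and selection-signature statistics (Weir–Cockerham Fst, EHH, iHS).
A synthetic-data module generates every input the pipeline consumes with
known ground truth, so the whole chain is testable end to end.

## The scientific problem

CFTR variants cause male infertility through congenital absence of the vas
deferens, but whether *common* CFTR variation shifts fertility in healthy
men requires a population with large families, minimal contraception, and
genealogy deep enough to model relatedness. In such a founder isolate, the
natural fertility phenotype of a married man with at least two children is
his **birth rate**

    r = (n_births − 1) / Σ interbirth intervals,

residualized on wife's birth year and years from marriage to last birth.
Relatives share both genes and environment, so association tests model the
phenotypic covariance as

    Σ = σ²_a · 2Φ + σ²_e · I,

with Φ the pedigree kinship matrix (A = 2Φ is the additive relationship
matrix). Variance components are fit by maximum likelihood under the
covariates-only null; genotype codings (general 2-df, recessive 1-df,
additive 1-df) are then tested by a GLS F-statistic

    F = [(RSS₀ − RSS₁)/q] / [RSS₁/(n − p₁)]

on the whitened scale, with percent variance explained
(RSS₀ − RSS₁)/RSS₀ × 100 and a Bonferroni correction min(1, p·n_tests).
A Wald-t on the additive coefficient reproduces the measured-genotype
replication-cohort analysis. Fertility differences between genotype groups
are also compared nonparametrically: Kaplan–Meier curves and the log-rank
test for time from marriage to the 6th birth (censoring at the last birth),
and a Wilcoxon rank-sum test for completed family size.

If a derived allele raises male fertility it should leave a sweep
signature. The package implements Weir–Cockerham's θ from two-population
allele counts, extended haplotype homozygosity EHH(x) (probability that two
random core-allele carriers are identical from the core SNP out to distance
x), the integrated areas iHH on each allelic background, the
unstandardized iHS = ln(iHH_ancestral / iHH_derived) (negative = long
derived haplotypes), its frequency-bin standardization, and empirical
marginal/joint tail fractions against genome-wide distributions.

## Worked example

Simulate a 13-generation isolate descending from 62 founders, give married
men a recessive ancestral-homozygote deficit of 0.049 births/yr at derived
allele frequency 0.29, and run the relatedness-corrected association:

```python
import numpy as np
from natfert.simulate import (PedigreeSimConfig, FertilitySimConfig,
                              simulate_pedigree, simulate_fertility)
from natfert.pedigree import kinship_matrix
from natfert.phenotypes import build_phenotypes
from natfert.association import estimate_variance_components, gls_association

simped = simulate_pedigree(PedigreeSimConfig(seed=42))
kin = kinship_matrix(simped.pedigree)
sim = simulate_fertility(simped, FertilitySimConfig(seed=42, n_men=204), kin=kin)

phenos, excluded = build_phenotypes(sim.histories)
ids = [p.individual_id for p in phenos]
y = np.array([p.rate for p in phenos])
hist = {h.individual_id: h for h in sim.histories}
X = np.column_stack([[hist[i].wife_birth_year for i in ids],
                     [hist[i].marriage_to_last_birth for i in ids]])
g = np.array([sim.dosages[i] for i in ids])

sub = kin.subset(ids)
vc = estimate_variance_components(y, X, sub.phi)
Sigma = vc.covariance(sub.additive())
for scheme in ("general", "recessive_met"):
    r = gls_association(y, X, g, scheme, Sigma, n_tests=4)
    print(f"{scheme:>13}: F = {r.statistic:.2f}, P = {r.p_value:.4f}, "
          f"Pc = {r.p_bonferroni:.4f}, %var = {r.pct_variance_explained:.2f}, "
          f"lower-fertility allele = {r.lower_fertility_allele}")
```

prints

```
      general: F = 2.92, P = 0.0563, Pc = 0.2253, %var = 3.18, lower-fertility allele = Met
recessive_met: F = 5.56, P = 0.0194, Pc = 0.0777, %var = 3.01, lower-fertility allele = Met
```

i.e. on this synthetic cohort of 183 phenotyped men the recessive contrast
(ancestral homozygotes vs carriers of the derived allele) detects the
planted deficit — the ancestral allele is the low-fertility allele, the
locus explains ~3% of the phenotypic variance — while the corrected
p-values illustrate the four-test Bonferroni penalty.

The same analyses run from the shell:

```sh
natfert simulate fertility --seed 7 --out demo          # synthetic bundle
natfert assoc  --pedigree demo/pedigree.ped --histories demo/histories.csv \
               --genotypes demo/genotypes.csv --out demo/results
natfert survive --histories demo/histories.csv --genotypes demo/genotypes.csv \
               --k 6 --out demo/results
natfert phase  --pedigree demo/pedigree.ped --genotypes demo/genotypes.csv \
               --out demo/results
natfert fst --n1 120 --x1 61 --n2 120 --x2 0
```

Every output table is TSV with a `#` provenance header (version, seed,
config hash); reruns with the same config and seed are byte-identical.

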