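# Methods

## Pedigree, kinship and gene drop

A pedigree is a validated DAG (distinct ids, both parents present or
neither, no individual its own ancestor; cycle, missing-parent and
duplicate-id defects raise distinct errors). Kinship uses the classical
recursion computed by dynamic programming over a topological order:
φ(i,i) = ½(1 + φ(f_i, m_i)) and, for j processed before i,
φ(i,j) = ½(φ(f_i, j) + φ(m_i, j)). This is exact, O(n²) time and memory,
and comfortable at the few-thousand-individual scale of founder-population
studies; path-counting or sparse methods would only pay off far beyond
that. Founders are assumed unrelated and non-inbred; sex is ignored
(autosomal locus), so unknown-sex parents are allowed. The inbreeding
coefficient is f_i = φ(father_i, mother_i); the association machinery uses
A = 2Φ (diagonal 1 + f).

Gene drop simulates Mendelian transmission: founder alleles i.i.d.
Bernoulli(p), each non-founder allele a uniform copy of one of the
corresponding parent's two. Allele pairs are ordered (paternal, maternal)
internally and unordered at I/O. The tests validate kinship against an
independent Monte-Carlo oracle that drops *unique* founder allele labels
and estimates φ as the probability that single sampled alleles are
identical by descent (10⁵ replicates; the binomial-SE acceptance band is
Bonferroni-widened across matrix entries so the family-wise level equals a
single 3-SE check).

## Birth-rate phenotype

For a man with at least two children, rate = (n − 1)/Σ interbirth gaps;
the gaps telescope to the first-to-last-birth span and both computations
must agree exactly. Men with fewer than two births, or twin-only histories
with zero span, yield an exclusion signal rather than an error. Years are
decimal throughout (month-resolution dates are converted upstream); output
metadata records the choice. Residualization is a single OLS of rate on
wife's birth year and years from marriage to last birth over all
phenotyped men jointly (complete cases; rank-deficient designs are
rejected); residuals are mean-zero and orthogonal to the covariates by
construction. A Shapiro–Wilk-based normality report (skewness, excess
kurtosis, p-value, degenerate flag) is advisory and never blocks a run.

## Relatedness-corrected association

Model: y ~ N(Xβ, σ²_a·2Φ + σ²_e·I). The ML variance components are
profiled over h = σ²_a/(σ²_a + σ²_e) using the eigendecomposition of 2Φ
(grid over [0, 1) then bounded refinement; a flat likelihood — e.g. all
individuals unrelated — resolves to the h = 0 boundary by a parsimony
tie-break). A dominance component σ²_d·Δ is deliberately not included by
default: additive-plus-environment is the minimal faithful covariance
model, and the choice is visible in the result metadata. Components are
estimated once under the covariates-only null and the resulting Σ is
reused for every genotype coding at the locus (standard measured-genotype
practice; avoids per-model refit instability).

Codings at a biallelic locus with derived-allele count g: `general`
= {g, 1[g = 1]} (2 df), `recessive_met` = {1[g ≥ 1]} (1 df, ancestral
homozygotes vs carriers), `additive` = {g}. Coding columns that are
constant or collinear with the base design (e.g. no derived-homozygote
class in a small cohort) are dropped with a warning rather than failing.
Both models are whitened by the Cholesky factor of Σ and fit by least
squares; the F-statistic compares null and alternative RSS on the whitened
scale, so Σ = σ²I reproduces OLS exactly for any σ². The default fit is
joint (covariates + genotype in the alternative model); the residual-first
variant is available by passing the residual as the phenotype with no
covariates. Percent variance explained is (RSS₀ − RSS₁)/RSS₀·100 on the
same whitened fits; the Bonferroni correction is min(1, p·n_tests) with
n_tests = 4 by default (two codings at the missense SNP, one test at each
repeat locus). Any further within-locus correction of the original
regression framework is left as a documented no-op hook. The Wald-t
variant reports t = β̂/SE(β̂) for the additive coefficient with Σ from the
null-model components — the replication cohort's measured-genotype
analysis. Effect direction is reported as the allele associated with lower
fertility (sign of the carrier/additive coefficient).

## Survival comparison

Time from marriage to the kth birth (k = 6 by default, the cohort's mean
and median family size); men with fewer than k births are censored at
their last birth — implemented literally, even when the marriage continued
afterwards. Kaplan–Meier estimation and the log-rank chi-square/p-value
are delegated to lifelines (events precede censorings at tied times, the
standard product-limit convention); the per-group observed/expected event
table is computed in-package with hypergeometric expectations and
satisfies Σ(O − E) = 0. Completed family sizes are compared by the
Wilcoxon rank-sum test (exact enumeration when the combined sample is
≤ 12 without ties, tie-corrected normal approximation otherwise). The
"married at least the average reproductive period" filter recomputes its
threshold as the sample mean marriage-to-last-birth span of the input
cohort. The cumulative summary reports, per genotype group and birth
order b, the mean and SE of the marriage-to-bth-birth wait among men with
at least b births (SE flagged undefined below two contributors).

## Haplotype phasing and LD

Intron-8 (TG)m–polyT diplotypes arrive phased from single-amplicon
sequencing and are passed through verbatim; the phasing problem is
attaching Met/Val to the two intron-8 haplotypes. Phase is assigned only
by observation: homozygosity at either system forces it, otherwise
Mendelian transmission between genotyped relatives may. The implementation
is constraint propagation to a fixed point: candidate unordered haplotype
pairs per individual are pruned against what each genotyped parent could
transmit, and parents against what their children must have received,
iterating family-wise until nothing changes — so newly phased parents
phase children (and vice versa) and the result is independent of
processing order. An empty candidate set raises an error naming the trio.
Individuals with more than one surviving pair stay ambiguous; statistical
(EM) phasing is deliberately not used, mirroring the observational design
(one double-heterozygous man without informative relatives remains
unresolved, as in the source cohort). Haplotype frequencies are counts
over resolved individuals (ambiguous count reported). D′ requires an
explicit dichotomization of each multi-allelic locus (e.g. 7T vs rest ×
Val vs Met); D = p_AB − p_A p_B is normalized by its frequency-bounded
maximum, and r² is reported alongside.

## Selection statistics

Weir–Cockerham θ for two populations is computed from allele counts in the
haploid ANOVA (allele-frequency) form θ = (MSP − MSG)/(MSP + (n_c − 1)MSG)
— the form appropriate when only allele frequencies, not genotypes, are
available; a genotype-level variant with the observed-heterozygosity a/b/c
components is provided and labelled, since published Fst values do not
always state which was used. The estimator is unbiased, hence slightly
negative (−1/(n_c − 1)) at zero differentiation and exactly 1 at opposite
fixation; a both-monomorphic input returns an explicit undefined flag.

EHH among the n_c carriers of a core allele is Σ_h C(n_h, 2)/C(n_c, 2)
over identical-prefix classes from the core out to each marker, computed
separately upstream and downstream (non-increasing by construction,
EHH(0) = 1). iHH integrates each curve by trapezoids over physical
distance (genetic-map distance when supplied), truncating after the first
segment that falls below the cutoff (default 0.05); curves that never
reach the cutoff inside the panel set an edge-truncated flag. The
unstandardized iHS is ln(iHH_ancestral/iHH_derived), negative when the
derived background carries the longer haplotypes, and exactly
antisymmetric under allele relabelling. Standardization is a z-score
within derived-allele-frequency bins (default 20 equal-width bins on
(0,1)); bins with fewer than two distinct values are merged into the
nearest usable neighbor and the merges reported. Missing alleles in
panels are rejected at load. Empirical percentiles report marginal
fractions P(Fst ≥ t) and P(iHS ≤ s) and, for per-SNP paired
distributions, the joint fraction; zero fractions are flagged as below
1/N resolution.

## Synthetic data

The generators emulate the study setting with known truth; all are
deterministic given (config, seed).

* **Pedigree**: founder couples (defaults 62 founders, 13 generations),
  Poisson sibships (mean 4), within-generation mating capped at
  n_founders/2 couples per generation, first-cousin mating preferred with
  probability 0.15 (sib matings never occur). With cousin mating disabled
  the population is kept fully outbred: mates must share no ancestry, and
  an unrelated immigrant founder marries in when no such partner exists —
  so every inbreeding coefficient is exactly 0 in that mode. A generation
  with no mateable pairs raises an extinction error suggesting larger
  sibships.
* **Fertility**: latent rate = μ + genotype effect + covariate terms +
  polygenic draw (covariance σ²_a·2Φ via Cholesky) + N(0, σ²_e); defaults
  are the study conditions — recessive ancestral-homozygote deficit 0.049
  births/yr at derived frequency 0.29, μ = 0.49, h² = 0.2, exposure
  duration N(11.5, 5²) years truncated to [2, 30]. Wife's birth year is
  the husband's plus small noise, reproducing the near-unit coupling of
  spousal birth years. Birth years are marriage plus cumulative Gamma
  interbirth gaps with mean 1/rate (shape 4 by default: realistic
  dispersion while keeping the rate recoverable). Genotypes come from a
  **conditional gene drop**: because drift through a deep founder pedigree
  scatters the cohort allele frequency widely around the founder
  frequency, transmission is redrawn (seeded, bounded tries) until the
  phenotyped cohort's frequency is within ±0.03 of the target — the
  cohort frequency, not the founder frequency, is the stated study
  condition. A whole-haplotype drop with arbitrary labels provides
  three-locus genotypes with known true phase for the phasing tests.
* **Two-population counts**: binomial draws at specified frequencies.
* **Sweep panel**: 120 haplotypes × 1001 SNPs at 1 kb spacing (a ±500 kb
  window), derived-core frequency 0.5; derived haplotypes copy a single
  template over a 600 kb tract centred on the core with 2% per-site
  mutation noise, ancestral haplotypes (and everything outside the tract)
  are site-independent draws at matched frequencies. Tract 0 gives an
  exchangeable null panel.

What the generator does *not* emulate: recombination and linkage between
the fertility locus and the genome (the polygenic term is drawn from the
pedigree covariance directly), age structure and remarriage, secular
fertility trends, genotyping error, and coalescent-realistic haplotype
panels (the sweep panel is a stylized template-copy construction). Passing
tests therefore certify the estimators and the pipeline plumbing under the
stated covariance and transmission models, not robustness to those
real-data features.

### Measurement attenuation and the recovery designs

The measured rate (n − 1)/span is a noisy, selection-filtered estimate of
the latent rate: finite observation windows, the ≥2-births qualification
and finite birth counts attenuate any genotype contrast on the measured
scale by roughly 15–20% under the default exposure distribution (the
latent-rate oracle recovers the injected deficit exactly). This is a
property of the phenotype definition, not of the estimators. The
parameter-recovery checks (recessive effect, effect direction,
heritability) therefore measure rates over long marriages with
low-dispersion intervals (exposure N(25, 3²), Gamma shape 16) while
keeping the named conditions (n = 204, frequency 0.29; h²) — isolating
the estimator property from measurement error. Calibration checks (type-I
error, log-rank null) and the direction-of-effect pipeline demonstration
run under the default study conditions.

## Problem sizes and numerical choices

The shared test substrate is one simulated isolate (62 founders, 13
generations, ≈1,600 individuals) and its exact kinship matrix. Type-I
calibration uses 2,000 null replicates at n = 200 with the true Σ
(rejection 0.05 ± 0.01, plus a KS uniformity check); log-rank calibration
2,000 replicates of two exponential groups of 40; effect recovery 25–60
seeds at n = 204; heritability recovery 20 seeds at n = 300–500; sweep
sign recovery 100 panels; the IBD kinship oracle 10⁵ gene drops. Jitter of
1e-10 is added before Cholesky of 2Φ (semidefinite for inbred pedigrees);
the VC profile uses a 101-point grid with 1e-6 bounded refinement;
genotype-coding columns are checked for rank against the base design
before fitting. The acceptance script (`scripts/acceptance.py`) re-runs
the whole set from a single seed in under a minute.
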