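# Methods

## Data model and conventions

A cohort is a samples × SNPs matrix of minor-allele counts {0, 1, 2}
with `NaN` for missing calls, a binary disease phenotype, and three
adjusting covariates: age (years), gender (binary) and ever-smoking
(binary). All genomic coordinates are 1-based inclusive internally; BED
input is converted at the boundary (start = BED start + 1). The coded
allele is intended to be the minor allele: VCF input is re-oriented at
load time on the full pre-QC sample (dosages flipped when the ALT
frequency exceeds 0.5), while TSV input is trusted as minor-coded so
that write-then-read round-trips are exact. Missing tokens are `NA`
(TSV) and `./.` (VCF). Strand is stored for provenance but ignored by
mapping, because the ±flank window is symmetric.

## SNP quality control

A SNP is retained iff MAF ≥ 0.05 **and** call rate ≥ 0.95 **and**
exact-HWE p > 10⁻⁴. Boundary semantics are deliberate and asymmetric:
the MAF and call-rate thresholds keep the boundary value ("less than
5% … excluded"), the HWE threshold drops it ("p ≤ 10⁻⁴ excluded").
The HWE test is the exact conditional test — enumerate every
heterozygote count compatible with the observed allele counts, and sum
the probabilities of all configurations no more probable than the
observed one — computed in log space with a 10⁻¹⁰ log-tolerance for
floating ties. The exact test is preferred over the χ² approximation
because the filter operates at the 10⁻⁴ tail, where the approximation
is unreliable, and because the exact form is verifiable against a
rational-arithmetic oracle. HWE is evaluated in controls only by
default (cases may deviate through genuine association); an
`all`-samples option exists. Sample-level QC is assumed done upstream;
`apply_qc` never drops samples. Failure reasons record *every* violated
filter, and re-running QC on its own output is a fixed point.

## Per-SNP association

Logistic regression of status on intercept + coded genotype + age +
gender + smoking, under additive (0/1/2) and dominant (0/1/1) codings.
The recessive coding is not offered: with low minor-allele frequencies
the homozygous-minor class is too sparse to be informative. Samples
with a missing genotype are deleted casewise per SNP (no imputation) in
the maximum-likelihood path.

Three routes produce the same quantity at different scales:

* `fit_snp_logistic` — statsmodels ML fit, one SNP at a time; the
  reference implementation and the one used for reported tables.
* `batch_logistic_wald` — Newton/IRLS vectorized across SNPs (the
  per-SNP 5×5 normal equations are assembled with einsum and solved in
  a batch). Convergence: relative log-likelihood change < 10⁻⁸, at most
  100 iterations; |β̂| > 15 is treated as separation. Flagged SNPs
  (monomorphic-in-analysis, separated, non-converged) report p = 1 and
  are ineligible for best-SNP selection. Agreement with statsmodels is
  tested to ~10⁻⁵ on the coefficients.
* `batch_logistic_score` — Rao score test against the covariate-only
  null: one small IRLS fit per phenotype column, then two matrix
  products for all SNPs. Missing genotypes are mean-imputed on this
  path (the standard fast-GWAS convention); this is the one place the
  casewise-deletion rule is traded for speed, and it is applied
  identically to observed and permuted columns, so permutation p-values
  remain exchangeable and calibrated. Score z and Wald t agree to
  |Δ| < 0.05 on clean data in the tests.

The statistic handed to the ranking is |t| — risk and protective
alleles both signal association, and enrichment is direction-agnostic.
ARTP consumes the matching two-sided p, so both methods see the same
best SNP per gene (|t| and p order identically within a column).

Demographic odds ratios (the cohort-description table) use the closed
2×2 cross-product form with Wald intervals, with an optional +0.5
continuity correction for zero cells; the multivariate column is a
single statsmodels logistic fit.

## Gene mapping and set structure

SNP s maps to gene g iff chrom(s) = chrom(g) and
start(g) − 20000 ≤ pos(s) ≤ end(g) + 20000, boundaries inclusive.
A SNP may map to several genes. Genes with no mapped SNP are recorded
as unmappable and removed from gene sets. Best-SNP selection takes the
maximum |t| (equivalently the minimum p) among a gene's eligible SNPs,
breaking ties by smaller position, then lexicographic SNP id.

Pathway membership is intersected with the mappable gene universe
*before* the 20–200 size filter is applied; the filter therefore counts
the genes the statistic actually sees. This choice (raw-vs-mappable
counting is genuinely open) keeps the filter meaningful when marker
coverage is sparse.

Pathway overlap is 100·|A∩B|/min(|A|,|B|) percent: 100% iff one set
contains the other. Superset elimination runs on intersected
membership: among candidates, equal sets keep the first in catalog
order, then every strict superset of any surviving set is removed
(chains A ⊂ B ⊂ C lose both B and C), and each removal is logged with a
justifying subset. A strict-subset test is used rather than an overlap
threshold; with 100% overlap defined as containment the two coincide.

## Permutation engine

B unrestricted permutations of the phenotype vector (covariates and
genotypes stay attached to samples); column 0 is the identity
permutation and flows through the identical code path, so it reproduces
the observed statistics bit-for-bit — a property the tests assert. For
each column the per-SNP association and the best-SNP reduction are
recomputed, and the *same* columns feed both GSEA and ARTP. Because an
unrestricted shuffle destroys the covariate–phenotype association (the
permuted-data refit still adjusts for covariates), a stratified option
shuffles labels within gender × smoking strata; it is off by default to
follow the plain phenotype-permutation scheme of the source methods.
The default statistic path for permutation runs is the score test;
`wald` refits everything exactly and is intended for small data.

## GSEA screening

With genes ranked by best-SNP |t| descending (stable sort, tie-break by
gene symbol ascending), the running sum adds |r_j|^w / N_R on pathway
hits (N_R = Σ_hits |r|^w) and subtracts 1/(N − N_H) on misses; ES is
the signed maximum of the running sum — enrichment at the top of the
list is the hypothesis, so the maximum absolute deviation variant is
not used. The weight is w = 1 (configurable); at w = 1 the ES is
invariant to rescaling all statistics. Genes missing in a column (all
SNPs flagged) are dropped from that column's ranking, shrinking N and
N_H accordingly. If every member statistic is exactly zero the hit
increments degenerate to 1/N_H.

NES standardizes the observed ES by the mean and sample SD (ddof = 1)
of the pathway's B permuted ES values; permuted ES are standardized by
the same moments for the FDR pool. Nominal p uses the add-one
estimator (1 + #{ES_perm ≥ ES_obs})/(B + 1), bounded below by
1/(B + 1). FDR for a pathway with observed NES\* is the pooled fraction
of permuted NES ≥ NES\* divided by the fraction of observed NES ≥
NES\*, evaluated on the positive-enrichment side only (non-positive
NES\* gets FDR 1), clamped to [0, 1].

Screening: a pathway is a candidate iff nominal p ≤ 0.025 **and** FDR ≤
0.25 in the additive *or* the dominant model (inclusive boundaries).

## ARTP validation

Per pathway and column, the member genes' best-SNP p-values are sorted
ascending and W(K) = Π_{i≤K} P_i is accumulated as a sum of logs. The
default truncation set is K ∈ {1, 2, 3, 4, 5, 10, 15, 20} ∩ {1..L}
(the original truncation grid is unstated; this covers single-gene
through broad-signal regimes for 20–200-gene sets and is configurable).
The per-K significance of column b is its add-one rank among all other
columns; the adaptive statistic is the minimum over K; the adjusted p
is the permutation rank of the observed adaptive statistic. One shared
permutation layer serves every K and every pathway. Genes missing a
usable p in a column are skipped in that column's sort, with K clamped
to the usable count. Validation: adjusted p ≤ 0.01 in either model.
Note the threshold is attainable only when B ≥ 100 (minimum adjusted p
is 1/(B+1)).

A discordance report flags candidates that passed the GSEA screen in a
model whose ARTP p in the same model misses the threshold; the pipeline
excludes discordant candidates before overlap pruning, mirroring the
screening-then-validation logic the thresholds were designed for.

## Positive controls

Six benchmark gene sets are packaged: a 32-symbol master list of
reported lung-cancer susceptibility genes (ILCCO candidates, NSCLC
driver-mutation genes, GWAS locus genes at 3q28-29/5p15/6p21/15q25,
DNA-repair genes) and five leave-one-locus-out derivatives. The
published summary table counts the master set as 29 genes while its
footnote enumerates 32 symbols; both numbers are kept as data
(`MASTER_REPORTED_COUNT`) and no synonym resolution is attempted.
`calibrate_thresholds` is purely descriptive: it reports the p/FDR
ranges the control sets achieve and the fraction admitted by the
default thresholds, which it never changes.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

* **Genotypes** — per SNP, binomial(2, MAF) in HWE, MAF ~ U(0.05, 0.5),
  independent across SNPs by default. An optional within-gene
  copy-with-flip LD mode exists for robustness exercises only; the
  statistics use one SNP per gene, so LD chiefly perturbs best-SNP
  selection.
* **Genome** — genes of 5–50 kb on synthetic chromosomes with 60 kb
  gaps, so ±20 kb windows never span two genes and mapping behaviour is
  fully controlled; SNP counts per gene default to U{2..12} (of the
  order of the ~10 mapped SNPs per gene a 500K array yields).
* **Pathways** — gene sets sampled from the shared pool (default 40
  sets of 25 from 300 genes); pathways 0 and 1 are drawn from disjoint
  halves of the pool, and a subset child of pathway 0 (80% of its
  genes) is appended, guaranteeing one disjoint pair and one strict
  subset pair for the overlap/pruning machinery. `plant_superset_pathway`
  adds strict supersets on demand.
* **Phenotype** — covariates first (age U{40..75}, gender Bern(0.55),
  smoking Bern(0.5)), then case status by rejection sampling from
  logit P = β₀ + Σβ_g·g + β_age·age + β_gender·gender + β_smk·smoking.
  Default covariate ORs 0.48 (gender), 0.52 (smoking), 0.98 (per year)
  mirror the multivariate demographic profile of the Korean NSCLC
  panel the package models; default size is 869 cases / 1,533 controls.
  β₀ is calibrated by bisection on a dedicated 20,000-draw sample so
  the expected case fraction matches the design; unattainable designs
  raise a calibration error. Causal effects (default per-allele OR 1.5
  in half of a designated pathway's genes, one causal SNP per causal
  gene) are planted only when requested; the truth record lists every
  planted β, SNP, gene and pathway.
* **Missingness** — uniform at random, default 1%.

All randomness derives from one `numpy` generator seeded by the config;
identical configs give byte-identical output files.

What the generator does *not* emulate — and what passing tests
therefore do not certify on real data: linkage disequilibrium between
genes and realistic LD within them, population stratification and
relatedness, genotyping batch/platform artifacts, informative
missingness, covariate–genotype correlation (e.g. smoking-linked
loci), and realistic MAF spectra. Cross-platform harmonization of
merged arrays is likewise out of scope.

## Numerical choices

* Logistic IRLS: relative log-likelihood tolerance 10⁻⁸, max 100
  iterations, separation at |β̂| > 15; weights floored at 10⁻¹² to keep
  the batch Hessians well-posed.
* HWE enumeration: log-space with `logsumexp`; tie tolerance 10⁻¹⁰ on
  log-probabilities.
* RTP products as sums of logs; p-values floored at 10⁻³⁰⁰ before
  logging.
* Add-one estimators everywhere a permutation rank becomes a p-value,
  so no p is ever 0 and the minimum is 1/(B + 1).
* Ranking ties: stable sort with gene-symbol tie-break; best-SNP ties:
  position then SNP id. Both make permutation columns reproducible.
* Rendered tables format floats as `%.6g`, making end-to-end reports
  byte-identical under a fixed seed.

## Problem sizes used by the test suite

The suite exercises desk-scale configurations chosen to make the
statistical checks decisive: null calibration uses six global-null
cohorts of 2,000 samples × ~600 SNPs × 41 pathways at B = 200 (~240
replicate pathways; rejection rates at α ∈ {0.01, 0.05} checked against
95% binomial intervals); planted-pathway recovery uses 50 replicates of
2,000 samples with per-allele OR 1.5 in half of a 25-gene pathway at
B = 200; parameter recovery uses a single 20,000-sample cohort. Full
B = 1,000 runs (the analysis default) are available by config.

## Known limitations

* The score fast path's mean imputation slightly attenuates signals at
  SNPs with many missing calls; the Wald path is exact but slow for
  permutation runs.
* The permutation FDR estimator is noisy for small pathway collections
  (a handful of observed NES values) and is clamped rather than
  monotonized.
* Unrestricted phenotype permutation breaks covariate–phenotype
  association in the null; the stratified option trades that fidelity
  for a coarser permutation group.
* The two-stage screen (GSEA) then validation (ARTP) reuses the same
  permutations and the same data for both stages; the thresholds are
  calibrated jointly by design, not corrected for the two-step
  selection.
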