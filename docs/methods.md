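# Methods

## Study design and case definition

fibrosnp analyses retrospective case-control panels in which the
phenotype is late radiation-induced subcutaneous/deep-tissue fibrosis
scored on the RTOG/EORTC 0–4 scale.  Grade 3–4 defines the
radiosensitive cases, grade 0–2 the controls; the mapping is a pure
function and a patient without a valid integer grade is rejected at
load time rather than silently dropped, because the grade *is* the case
definition.  Genotypes are carried as variant-allele dosage (0/1/2
copies of allele 2, the minority allele), the minimal lossless
per-patient representation: allele counts, genotype histograms and the
burden score are all derived from it.  Missing genotypes are excluded
per SNP from allele tables (complete-case per marker).

## Allele-level association

Each patient contributes two alleles, giving the 2×2 table
(a, b; c, d) = (case allele-1, case allele-2; control allele-1,
control allele-2).

**Effect size.**  The primary effect is the variant-allele odds ratio
OR = (b·c)/(a·d), with the Woolf (log-normal) interval
exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)).  Zero cells are dispatched
rather than corrected:

* b > 0, d = 0 (variant in cases only): the OR is infinite, so the
  effect falls back to the risk ratio of case status among
  variant-allele versus wild-type-allele carriers,
  RR = [b/(b+d)]/[a/(a+c)], with the Katz interval
  exp(ln RR ± z·√(1/b − 1/(b+d) + 1/a − 1/(a+c))).
* b = 0, d > 0 (variant in controls only): reported as effect 0 with
  no interval, matching the conventional table rendering.
* b = d = 0 (monomorphic): undefined; no test is run.

A Haldane–Anscombe 0.5-corrected OR is available behind a flag for
sensitivity analyses but is never used by default: the zero-cell
renderings above are the convention this class of study reports.

**Test selection.**  Pearson's χ² (1 df, *no* Yates continuity
correction; the corrected statistic is available behind a flag) is used
when Cochran's criterion holds — every expected cell count
E = row·col/N ≥ 5 and no zero margin — and the two-sided Fisher exact
test otherwise.  On the packaged reference tables this rule reproduces
exactly the published chi-square/Fisher assignment (all twelve
Fisher-marked rows and no others) and every chi-square p-value at
two-decimal precision, which is the evidence for adopting it.  The
Fisher two-sided p uses the minimum-likelihood convention (sum of
point probabilities ≤ the observed table's); the tail-doubling
convention of some legacy 2×2 calculators is available behind a flag.
The two conventions differ materially away from the tail (doubling
caps at 1 for near-null sparse tables where minimum-likelihood gives
≈ 0.52), which is why the agreement between χ² and exact p is only
asserted in the rejection tail (cells ≥ 30, exact p ≤ 0.1, |Δp| <
0.03); no flat agreement band holds across the whole p range.

**Multiplicity.**  Nominal significance is p ≤ α (α = 0.05 by
default).  The Bonferroni threshold is α/m with strict comparison
p < α/m; m defaults to the number of SNPs with any variant allele
observed (29 of 45 on the reference panel), since monomorphic markers
contribute no comparison, and is configurable because reasonable
analysts disagree between "all assessed" and "all informative".

**HWE QC.**  An exact Hardy–Weinberg test (conditional enumeration of
heterozygote counts given allele counts, two-sided by point-probability
ordering) is provided for per-group genotype QC; monomorphic samples
give p = 1.

## Risk-allele burden

SNPs with p ≤ 0.05 (the ≤ gate is deliberate where prose elsewhere
wavers between < and ≤) and a defined, directional effect enter the
risk model: effect > 1 designates the variant allele as the risk
allele, effect < 1 the wild-type allele.  An effect of exactly 1 is
directionless and excluded.  The per-patient score sums risk-allele
copies over model SNPs — dosage where the risk allele is the variant,
2 − dosage where it is the wild type (the complement formula protective
variants imply).  Patients missing a genotype at any model SNP are
flagged and excluded from the comparison by default; mean imputation
exists behind a flag only.

Group comparison uses the two-sided Mann–Whitney U test: the exact null
distribution when the pooled scores are tie-free and n₁·n₂ ≤ 10⁴,
otherwise the normal approximation with tie-corrected variance and
continuity correction (integer burden scores are heavily tied, so real
cohorts take the asymptotic path).  A fully tied comparison (every
score identical) is reported as U = n₁n₂/2, p = 1.  Box-plot summaries
(median, quartiles, 10th/90th percentiles, range) are computed per
group.

## The simulator

The generator draws, per SNP, control dosages Binomial(2, q) — HWE at
the control variant-allele frequency q — and case dosages
Binomial(2, q′) with q′ implied by the per-allele odds ratio:
odds′ = OR·q/(1−q), q′ = odds′/(1+odds′).  This retrospective
allele-odds construction (rather than prospective logistic sampling)
makes the simulated OR exactly the estimand of the Woolf odds ratio, so
parameter-recovery tests are unbiased by design rather than
approximately.  SNPs are simulated independently: the analysis is
marginal per SNP, and linkage disequilibrium is out of scope.  Grades
are drawn from per-group mixtures; defaults reproduce the reference
cohort's histogram (17, 54, 36 over grades 0–2 in controls; 38, 10
over 3–4 in cases) and group sizes (48/107).  The panel frequency
field is a variant-allele frequency in [0, 1] rather than a minor-allele
frequency capped at 0.5, because one reference marker's variant allele
has control frequency 0.52.  Requesting an effect (OR ≠ 1) on a
monomorphic SNP (q ∈ {0, 1}) is a configuration error — no frequency
shift can be realised.  All sampling flows from one
`numpy.random.default_rng(seed)`; identical configs give bit-identical
cohorts.

What the simulator does *not* emulate: genotyping error, missingness
patterns, LD between neighbouring SNPs in the same amplicon, population
stratification, and covariates (dose, chemotherapy).  Passing tests
therefore demonstrate the statistical machinery is correct under the
stated sampling model, not that the design is robust to those
real-data complications.

## Numerical and reporting conventions

* All internal arithmetic is full double precision; rounding happens
  only at the formatting layer, half away from zero (1.275 → 1.28),
  at 2 decimals for effects/CIs/p-values and to the integer for
  percentages.  A percentage that would collapse to 0 or 100 while its
  count is neither zero nor the full margin is kept at 0.5 granularity
  (213/214 → 99.5), mirroring the reference table's rendering.
* p-values below 0.01 display as "<0.01"; Fisher-tested rows carry a
  "*" marker and risk-ratio fallbacks "**", with footnotes.
* z for 95% intervals is Φ⁻¹(0.975) (= 1.959964), not 1.96; the
  difference is invisible at report precision.
* Exact-test p ordering uses a 1 + 10⁻¹² relative tolerance when
  comparing point probabilities, so ties of probability mass are
  included as ties rather than lost to floating-point noise.

## Validation problem sizes

The test suite validates the core against independent brute-force
oracles (exact rational hypergeometric enumeration for Fisher, explicit
expected-count loops for χ², full permutation enumeration for the
Mann–Whitney exact path, token-counting for burden scores) and
cross-checks Woolf/Katz intervals against statsmodels' 2×2 machinery.
Calibration experiments use: 1000 null replicates of the full
48/107 × 45-SNP design for type-I error (chi-square-tested markers
expected in 0.05 ± 0.02; sparse Fisher-tested markers conservative);
100 000 patients per group for parameter recovery (|ln OR error| < 0.05,
a tolerance several Monte-Carlo standard errors wide at that n); 200
seeds for the case-vs-control burden-median shift under the six-SNP
effect model; and 500 null replicates for uniformity of burden-test
p-values (Kolmogorov–Smirnov at α = 0.01).

## Known limitations

* Genotype-level (2×3) models, covariate-adjusted logistic regression
  and haplotype analysis are out of scope; association is allele-based
  and marginal.
* The allele-level test treats a patient's two alleles as independent
  observations, which is standard for this design but assumes HWE-like
  within-group allele pairing.
* Two published numbers are not exactly recoverable from the published
  counts under any convention tried (one OR printed 2.86 vs computed
  2.87; one CI bound printed 0.99 vs computed 1.00 at 2 dp); the
  package reports its computed values.
* The reference cohort's patient-level burden medians/ranges cannot be
  recomputed from group-level counts; the simulator-based checks stand
  in for them.
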